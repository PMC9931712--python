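"""End-to-end orchestration: simulate -> rates -> curves -> fit -> profile.

The pipeline is a plain sequence of library calls with no hidden state;
every stage writes its table under the output directory and the run ends
with a manifest (sha256 of each output, package version, seed) so reruns
with the same config are byte-for-byte reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cleavage import assign_peaks, enumerate_species, load_construct
from .energetics import build_profile
from .fitting import FitFailure, analyze_curve
from .fragments import curves_to_tsv, read_fragment_csv, residue_contents
from .intrinsic import compute_kch
from .peptide import PeptideSpec
from .simulate import generate_dataset, get_preset

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    preset: str | None = "hinge"          # simulate from a preset ...
    fragments_csv: Path | None = None     # ... or start from measured fragments
    peptide: PeptideSpec | None = None    # required with fragments_csv
    seed: int = 0
    noise_sigma: float = 0.01
    p_threshold: float = 0.01
    construct_yaml: Path | None = None
    peaks_csv: Path | None = None
    mass_tolerance: float = 1.0

    def validate(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p-threshold must lie in (0, 1)")
        for p in (self.fragments_csv, self.construct_yaml, self.peaks_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file missing: {p}")
        if self.fragments_csv is not None and self.peptide is None:
            raise ValueError("a peptide spec is required with external fragment data")
        if self.fragments_csv is None and self.preset is None:
            raise ValueError("either a preset or a fragment CSV must be given")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }

    # stage 1: data
    if config.fragments_csv is not None:
        fragments = read_fragment_csv(config.fragments_csv)
        peptide = config.peptide
        report["stages"].append("load")
    else:
        spec = get_preset(config.preset, seed=config.seed, noise_sigma=config.noise_sigma)
        generate_dataset(spec, out_dir=out)
        fragments = read_fragment_csv(out / "fragments.csv")
        peptide = spec.peptide
        report["stages"].append("simulate")

    # stage 2: intrinsic rates
    rates = compute_kch(peptide)
    rates.to_tsv(out / "rates.tsv")
    report["stages"].append("rates")

    # stage 3: residue curves
    curves = residue_contents(fragments, peptide)
    curves_to_tsv(curves, peptide, out / "curves.tsv")
    report["stages"].append("curves")

    # stage 4: kinetics
    fits = {}
    fit_rows = []
    for curve in curves:
        if not curve.fit_eligible():
            fits[curve.position] = None
            continue
        try:
            fits[curve.position] = analyze_curve(curve)
        except FitFailure:
            fits[curve.position] = None
        f = fits[curve.position]
        if f is not None:
            fit_rows.append(
                {
                    "position": curve.position, "model": f.model,
                    "k_slow": f.k_slow, "k_fast": f.k_fast,
                    "amp_slow": f.amp_slow, "amp_fast": f.amp_fast,
                    "se_log10_k_slow": f.se_log10_k_slow, "p_wilks": f.p_wilks,
                    "rss": f.rss, "n_points": f.n_points,
                    "flags": ";".join(f.flags),
                }
            )
    pd.DataFrame(fit_rows).to_csv(out / "fits.tsv", sep="\t", index=False,
                                  float_format="%.6g")
    report["stages"].append("fit")

    # stage 5: profile (restrict the rate table to fitted positions)
    fits_on_rates = {p: fits.get(p) for p in rates.positions()}
    profile = build_profile(
        peptide, fits_on_rates, rates,
        t_max=float(fragments["time_min"].max()),
    )
    profile.to_tsv(out / "profile.tsv")
    report["stages"].append("profile")

    # stage 6 (optional): cleavage-product assignment
    if config.construct_yaml is not None and config.peaks_csv is not None:
        construct = load_construct(config.construct_yaml)
        species = enumerate_species(construct)
        peaks = pd.read_csv(config.peaks_csv)
        assignments = assign_peaks(peaks, species, tolerance=config.mass_tolerance)
        assignments.to_csv(out / "assignments.tsv", sep="\t", index=False,
                           float_format="%.3f")
        report["stages"].append("assign-products")

    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.csv")):
        report["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
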