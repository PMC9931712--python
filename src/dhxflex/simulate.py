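"""Ground-truth DHX simulation under the two-state Linderstrom-Lang model.

Each backbone amide opens and recloses its H-bond (rates ``k_open``,
``k_close``) and exchanges its deuteron only while open (chemical rate
``k_ch``).  The deuteron survival of such an amide decays with the slow
eigenvalue of the two-state kinetic scheme,

    lambda = ( s - sqrt(s^2 - 4 k_open k_ch) ) / 2,   s = k_open + k_close + k_ch

evaluated here in the numerically stable form 2 k_open k_ch / (s + sqrt(...)).
Its limits are the classic exchange regimes: EX2 (k_close >> k_ch) gives
lambda ~ k_open k_ch / k_close and a well-defined opening free energy; EX1
(k_close << k_ch) gives lambda ~ k_open.  Amides visiting two conformers
with different opening equilibria produce weighted sums of two exponentials,
the generative mechanism behind biphasic exchange curves.

The generator converts per-residue models into cumulative c-/z-fragment
ladders on the 0.95/0.05 observable scale, adds seeded Gaussian noise, and
writes the ground truth (true slow rates, dG where EX2 holds, biphasic
labels) alongside, so every pipeline stage can be validated against known
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .energetics import R_KCAL
from .fitting import PLATEAU, SPAN
from .intrinsic import compute_kch
from .peptide import PeptideSpec, c99_tmd_peptide

#: k_close / k_ch ratio defining a clean EX2 conformer in the presets
EX2_CLOSE_FACTOR = 1000.0
#: k_close / k_ch ratio defining an EX1-like (correlated-exchange) conformer
EX1_CLOSE_FACTOR = 1e-3

DEFAULT_TIME_GRID = np.geomspace(0.1, 7 * 24 * 60.0, 12)  # 0.1 min .. 7 d
DEFAULT_NOISE_SIGMA = 0.01


def slow_eigenvalue(k_open: float, k_close: float, k_ch: float) -> float:
    """Slow relaxation rate of the two-state open/close/exchange scheme."""
    if min(k_open, k_ch) <= 0 or k_close < 0:
        raise ValueError("rates must be positive (k_close may be zero)")
    s = k_open + k_close + k_ch
    disc = s * s - 4.0 * k_open * k_ch
    return 2.0 * k_open * k_ch / (s + np.sqrt(max(disc, 0.0)))


@dataclass(frozen=True)
class Conformer:
    weight: float
    k_open: float
    k_close: float


@dataclass(frozen=True)
class ResidueModel:
    """Exchange model of one amide: one or two conformers sharing k_ch."""

    k_ch: float
    conformers: tuple[Conformer, ...]

    def __post_init__(self):
        if self.k_ch <= 0:
            raise ValueError("k_ch must be positive")
        w = sum(c.weight for c in self.conformers)
        if not np.isclose(w, 1.0):
            raise ValueError(f"conformer weights sum to {w}, expected 1")

    def eigenvalues(self) -> list[float]:
        return [slow_eigenvalue(c.k_open, c.k_close, self.k_ch) for c in self.conformers]

    def survival(self, times: np.ndarray) -> np.ndarray:
        """Deuteron survival fraction (1 at t=0), mixture over conformers."""
        t = np.asarray(times, float)
        out = np.zeros_like(t)
        for c, lam in zip(self.conformers, self.eigenvalues()):
            out += c.weight * np.exp(-lam * t)
        return out

    def observable(self, times: np.ndarray) -> np.ndarray:
        """Survival scaled to the 0.95/0.05 assay window."""
        return SPAN * self.survival(times) + PLATEAU

    @property
    def biphasic(self) -> bool:
        if len(self.conformers) < 2:
            return False
        lams = sorted(self.eigenvalues())
        return lams[-1] / lams[0] >= 10.0 and min(
            c.weight for c in self.conformers
        ) >= 0.1


def ex2_model(dg_kcal: float, k_ch: float, temperature: float) -> ResidueModel:
    """Single-conformer EX2 amide with the given opening free energy."""
    k_close = EX2_CLOSE_FACTOR * k_ch
    k_open = k_close * np.exp(-dg_kcal / (R_KCAL * temperature))
    return ResidueModel(k_ch=k_ch, conformers=(Conformer(1.0, k_open, k_close),))


def mixed_model(
    dg_kcal: float,
    k_ch: float,
    temperature: float,
    fast_factor: float = 100.0,
    w_fast: float = 0.5,
) -> ResidueModel:
    """Two-conformer amide producing biphasic exchange.

    The major EX2 conformer carries the stated dG; the second conformer
    exchanges in an EX1-like correlated mode with an effective rate
    ``fast_factor`` times the slow eigenvalue.
    """
    slow = ex2_model(dg_kcal, k_ch, temperature).conformers[0]
    lam_slow = slow_eigenvalue(slow.k_open, slow.k_close, k_ch)
    lam_fast_target = min(fast_factor * lam_slow, 0.5 * k_ch)
    # EX1: lambda ~ k_open when reclosing is much slower than chemistry
    fast = Conformer(w_fast, lam_fast_target, EX1_CLOSE_FACTOR * k_ch)
    return ResidueModel(
        k_ch=k_ch, conformers=(Conformer(1.0 - w_fast, slow.k_open, slow.k_close), fast)
    )


@dataclass
class SimulationSpec:
    """Everything needed to generate one synthetic DHX dataset."""

    peptide: PeptideSpec
    residue_models: dict[int, ResidueModel]
    time_grid: np.ndarray = field(default_factory=lambda: DEFAULT_TIME_GRID.copy())
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0

    def __post_init__(self):
        tg = np.asarray(self.time_grid, float)
        if not np.all(np.diff(tg) > 0):
            raise ValueError("time grid must be strictly increasing")
        self.time_grid = tg


def _per_residue_observables(spec: SimulationSpec) -> dict[int, np.ndarray]:
    """Observable content of every amide position (3..n) at the time grid.

    Unmodeled competent positions sit at the 0.05 plateau (already
    back-exchanged); positions 1-2 carry no signal by convention.
    """
    n = len(spec.peptide)
    out = {}
    for pos in range(3, n + 1):
        model = spec.residue_models.get(pos)
        if model is None or spec.peptide.sequence[pos - 1] == "P":
            out[pos] = np.full_like(spec.time_grid, PLATEAU)
        else:
            out[pos] = model.observable(spec.time_grid)
    return out


def truth_table(spec: SimulationSpec) -> pd.DataFrame:
    """Ground truth per modeled residue: rates, dG where EX2 holds, labels."""
    T = spec.peptide.temperature
    rows = []
    for pos in sorted(spec.residue_models):
        m = spec.residue_models[pos]
        lams = sorted(m.eigenvalues())
        slow_conf = min(
            zip(m.conformers, m.eigenvalues()), key=lambda cl: cl[1]
        )[0]
        ex2 = slow_conf.k_close >= 100.0 * m.k_ch
        dg = (
            -R_KCAL * T * np.log(slow_conf.k_open / slow_conf.k_close)
            if ex2
            else np.nan
        )
        rows.append(
            {
                "position": pos,
                "domain_position": spec.peptide.domain_position(pos),
                "k_ch": m.k_ch,
                "lambda_slow": lams[0],
                "lambda_fast": lams[-1],
                "biphasic_true": int(m.biphasic),
                "ex2_true": int(ex2),
                "dg_true": dg,
            }
        )
    return pd.DataFrame(rows)


def generate_dataset(spec: SimulationSpec, out_dir: str | Path | None = None) -> dict:
    """Simulate noisy c/z fragment ladders plus ground truth.

    Returns ``{"fragments": DataFrame, "truth": DataFrame}`` and, when
    ``out_dir`` is given, writes ``fragments.csv``, ``truth.tsv`` and the
    echoed spec as ``spec.yaml``.  Byte-identical outputs for equal seeds.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(spec.peptide)
    contents = _per_residue_observables(spec)

    rows = []
    for it, t in enumerate(spec.time_grid):
        c_cum = 0.0
        for i in range(2, n):  # c fragments c2 .. c_(n-1)
            c_cum = sum(contents[p][it] for p in range(3, i + 1)) if i >= 3 else 0.0
            rows.append(("c", i, t, c_cum))
        for j in range(1, n - 1):  # z fragments z1 .. z_(n-2)
            z_cum = sum(contents[p][it] for p in range(n - j + 1, n + 1))
            rows.append(("z", j, t, z_cum))

    df = pd.DataFrame(rows, columns=["frag_type", "frag_index", "time_min", "deuterons"])
    noise = rng.normal(0.0, spec.noise_sigma, size=len(df)) if spec.noise_sigma > 0 else 0.0
    df["deuterons"] = df["deuterons"] + noise
    df["sigma"] = spec.noise_sigma if spec.noise_sigma > 0 else 1e-6
    df["peptide_id"] = spec.peptide.id
    df["charge"] = 1
    df = df[["peptide_id", "time_min", "frag_type", "frag_index", "charge", "deuterons", "sigma"]]

    truth = truth_table(spec)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "fragments.csv", index=False, float_format="%.8g")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.8g")
        echo = {
            "peptide_id": spec.peptide.id,
            "sequence": spec.peptide.sequence,
            "numbering_offset": spec.peptide.numbering_offset,
            "ph": spec.peptide.pH,
            "temperature_k": spec.peptide.temperature,
            "noise_sigma": float(spec.noise_sigma),
            "seed": int(spec.seed),
            "time_grid_min": [float(x) for x in spec.time_grid],
        }
        (out / "spec.yaml").write_text(yaml.safe_dump(echo, sort_keys=False))
    return {"fragments": df, "truth": truth}


# ---------------------------------------------------------------------------
# preset library


def _kch_map(peptide: PeptideSpec) -> dict[int, float]:
    table = compute_kch(peptide)
    return {int(r.position): float(r.k_ch) for r in table.table.itertuples()}


def _hinge_spec(seed: int, noise_sigma: float) -> SimulationSpec:
    """C99-TMD-like helix: stable core, flexible di-glycine hinge, frayed ends.

    Core amides are clean EX2 with dG cycling through 4.0-5.5 kcal/mol (the
    working range of TMD flexibility profiles); the hinge (Abeta 36-39) mixes
    conformers at dG 3.5, and the outermost helix turns fray with conformer
    mixing at dG 2.5.
    """
    pep = c99_tmd_peptide()
    kch = _kch_map(pep)
    T = pep.temperature
    n = len(pep)
    hinge = {pos for pos in range(3, n + 1) if 36 <= pep.domain_position(pos) <= 39}
    frayed = {3, 4, 5, n - 2, n - 1, n}
    core_cycle = [4.0, 4.5, 5.0, 5.5]
    models: dict[int, ResidueModel] = {}
    for i, pos in enumerate(range(3, n + 1)):
        if pos in hinge:
            models[pos] = mixed_model(3.5, kch[pos], T)
        elif pos in frayed:
            models[pos] = mixed_model(2.5, kch[pos], T)
        else:
            models[pos] = ex2_model(core_cycle[i % len(core_cycle)], kch[pos], T)
    return SimulationSpec(pep, models, noise_sigma=noise_sigma, seed=seed)


def _rigid_spec(seed: int, noise_sigma: float) -> SimulationSpec:
    """Poly-Leu-like rigid helix: uniform dG ~ 6 kcal/mol, all monophasic."""
    pep = PeptideSpec(id="pL", sequence="KKK" + "L" * 24 + "KKK", numbering_offset=25)
    kch = _kch_map(pep)
    T = pep.temperature
    n = len(pep)
    flank = {3, 4, n - 1, n}
    models = {
        pos: ex2_model(2.0 if pos in flank else 6.0, kch[pos], T)
        for pos in range(3, n + 1)
    }
    return SimulationSpec(pep, models, noise_sigma=noise_sigma, seed=seed)


def _epsilon_spec(seed: int, noise_sigma: float) -> SimulationSpec:
    """Poly-Leu with a VGGV hinge and destabilized epsilon-site glycines."""
    tmd = list("L" * 24)
    for off, aa in zip(range(36, 40), "VGGV"):
        tmd[off - 29] = aa
    tmd[48 - 29] = "G"
    tmd[49 - 29] = "G"
    pep = PeptideSpec(
        id="pL-VGGV-epsGG", sequence="KKK" + "".join(tmd) + "KKK", numbering_offset=25
    )
    kch = _kch_map(pep)
    T = pep.temperature
    n = len(pep)
    models: dict[int, ResidueModel] = {}
    for pos in range(3, n + 1):
        dom = pep.domain_position(pos)
        if 36 <= dom <= 39:
            models[pos] = mixed_model(4.0, kch[pos], T)
        elif 47 <= dom <= 50:
            models[pos] = mixed_model(3.0, kch[pos], T)
        elif pos in (3, 4, n - 1, n):
            models[pos] = ex2_model(2.0, kch[pos], T)
        else:
            models[pos] = ex2_model(6.0, kch[pos], T)
    return SimulationSpec(pep, models, noise_sigma=noise_sigma, seed=seed)


_PRESETS = {
    "hinge": _hinge_spec,
    "rigid": _rigid_spec,
    "epsilon": _epsilon_spec,
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def get_preset(
    name: str, seed: int = 0, noise_sigma: float = DEFAULT_NOISE_SIGMA
) -> SimulationSpec:
    """Named simulation presets; unknown names raise with the valid listing."""
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {preset_names()}"
        ) from None
    return builder(seed=seed, noise_sigma=noise_sigma)
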