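"""Theoretical AICD/Abeta product masses and MALDI peak assignment.

Gamma-secretase cleaves the C99 transmembrane helix sequentially: initial
endoproteolysis at the epsilon sites (after Abeta residue 48 or 49) releases
the 51- or 50-residue APP intracellular domain (AICD51/AICD50), and stepwise
carboxyterminal trimming through zeta and gamma sites shortens the
N-terminal fragment toward Abeta37-Abeta42.  For a given construct this
module enumerates, per cleavage site, the N-terminal (Abeta-like) and
C-terminal (AICD-like) products with construct-appropriate tags, computes
average masses (MALDI-TOF linear mode of 4-12 kDa species reports average,
not monoisotopic, masses), and assigns observed singly-protonated peaks to
the nearest theoretical species within a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

# average residue (amino-acid minus water) masses, Da
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
H_MASS = 1.00794
OH_MASS = 17.00734
WATER = H_MASS + OH_MASS  # 18.01528
PROTON = 1.00794

#: APP C99 in Abeta numbering (D1 .. N99)
C99_SEQUENCE = (
    "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIATVIVITLVMLKKKQYTSIHHGVVEVDAAVTPEE"
    "RHLSKMQQNGYENPTYKFFEQMQN"
)
#: the TMD proper, Abeta G29..L52, replaced wholesale in the poly-Leu chimeras
C99_TMD_RANGE = (29, 52)

GSRS_LINKER = "GSRS"
HIS6 = "HHHHHH"

#: canonical sequential cleavage positions (cleave after this Abeta residue)
DEFAULT_SITES = {
    "eps49": 49, "eps48": 48, "zeta46": 46, "gamma43": 43, "gamma42": 42,
    "gamma40": 40, "gamma38": 38, "gamma37": 37, "gamma34": 34,
}


def average_mass(sequence: str, n_term_mod: str = "free_amine",
                 c_term_mod: str = "free_acid") -> float:
    """Average mass of a peptide: residue masses plus terminal groups.

    ``free_amine`` adds H at the N terminus, ``free_acid`` adds OH at the C
    terminus (together one water); ``none`` leaves the terminus bare, for
    composition arithmetic on fragment pairs.
    """
    mass = 0.0
    for i, aa in enumerate(sequence, start=1):
        try:
            mass += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {i}") from None
    if n_term_mod == "free_amine":
        mass += H_MASS
    elif n_term_mod != "none":
        raise ValueError(f"unknown N-terminal modification {n_term_mod!r}")
    if c_term_mod == "free_acid":
        mass += OH_MASS
    elif c_term_mod != "none":
        raise ValueError(f"unknown C-terminal modification {c_term_mod!r}")
    return mass


@dataclass(frozen=True)
class ConstructSpec:
    """A substrate construct and its cleavage-site catalog.

    ``full_sequence`` is the expressed protein (tags included);
    ``numbering_offset`` maps a domain (Abeta) position to the sequence index
    (seq_pos = domain_pos + offset); ``sites`` maps site names to the domain
    position after which the backbone is cut.
    """

    name: str
    full_sequence: str
    numbering_offset: int
    tmd_range: tuple[int, int] = C99_TMD_RANGE
    sites: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.tmd_range
        for site, pos in self.sites.items():
            if not lo <= pos <= hi:
                raise ValueError(
                    f"{self.name}: site {site} at {pos} outside TMD range {self.tmd_range}"
                )
            if not 1 <= pos + self.numbering_offset < len(self.full_sequence):
                raise ValueError(f"{self.name}: site {site} outside the sequence")

    def seq_index(self, domain_pos: int) -> int:
        return domain_pos + self.numbering_offset


def c99_variant_tmd(replacement: dict[int, str] | None = None,
                    poly_leu: bool = False) -> str:
    """C99 sequence with the TMD (Abeta 29-52) grafted.

    ``poly_leu=True`` replaces the whole 24-residue TMD by Leu before
    applying per-position ``replacement`` residues (domain numbering), the
    construction of the pL-GG / pL-VGGV / epsilon-GG / cleavage-region
    chimeras.
    """
    seq = list(C99_SEQUENCE)
    lo, hi = C99_TMD_RANGE
    if poly_leu:
        for p in range(lo, hi + 1):
            seq[p - 1] = "L"
    for pos, aa in (replacement or {}).items():
        if not lo <= pos <= hi:
            raise ValueError(f"replacement at {pos} outside TMD range")
        seq[pos - 1] = aa
    return "".join(seq)


def c100_his6_construct(name: str = "C100-His6",
                        tmd_replacement: dict[int, str] | None = None,
                        poly_leu: bool = False,
                        sites: dict[str, int] | None = None) -> ConstructSpec:
    """Recombinant substrate: N-terminal Met + C99 + GSRS linker + His6 tag."""
    body = c99_variant_tmd(tmd_replacement, poly_leu)
    return ConstructSpec(
        name=name,
        full_sequence="M" + body + GSRS_LINKER + HIS6,
        numbering_offset=1,  # Met is seq position 1, Abeta D1 is seq position 2
        sites=dict(sites if sites is not None else DEFAULT_SITES),
    )


# the TMD substitutions studied alongside wild-type C99
PL_VARIANTS = {
    "pL": dict(poly_leu=True),
    "pL-GG": dict(poly_leu=True, tmd_replacement={37: "G", 38: "G"}),
    "pL-VGGV": dict(poly_leu=True,
                    tmd_replacement={36: "V", 37: "G", 38: "G", 39: "V"}),
    "pL-VGGV-epsGG": dict(
        poly_leu=True,
        tmd_replacement={36: "V", 37: "G", 38: "G", 39: "V", 48: "G", 49: "G"},
    ),
    "pL-VGGV-cr": dict(
        poly_leu=True,
        tmd_replacement={36: "V", 37: "G", 38: "G", 39: "V",
                         44: "V", 45: "I", 46: "V", 47: "I", 48: "T",
                         49: "L", 50: "V", 51: "M", 52: "L"},
    ),
}


def standard_constructs() -> dict[str, ConstructSpec]:
    out = {"C99": c100_his6_construct("C99")}
    for name, kw in PL_VARIANTS.items():
        out[name] = c100_his6_construct(name, **kw)
    return out


def enumerate_species(construct: ConstructSpec) -> pd.DataFrame:
    """All N-/C-terminal products of the construct's cleavage-site catalog.

    Columns: species_name, site, side (N|C), sequence, length, avg_mass (Da,
    neutral).  The C-terminal product of an epsilon site is the AICD
    (eps49 -> AICD50, eps48 -> AICD51, lengths counted on the C99 body
    before tags); N-terminal products are named Abeta<site>.
    """
    rows = []
    seq = construct.full_sequence
    n_c99 = 99
    for site, pos in sorted(construct.sites.items(), key=lambda kv: kv[1]):
        cut = construct.seq_index(pos)
        n_seq, c_seq = seq[:cut], seq[cut:]
        rows.append(
            {
                "species_name": f"Abeta{pos}",
                "site": site,
                "side": "N",
                "sequence": n_seq,
                "length": len(n_seq),
                "avg_mass": average_mass(n_seq),
            }
        )
        rows.append(
            {
                "species_name": f"AICD{n_c99 - pos}",
                "site": site,
                "side": "C",
                "sequence": c_seq,
                "length": len(c_seq),
                "avg_mass": average_mass(c_seq),
            }
        )
    return pd.DataFrame(rows)


def assign_peaks(peaks: pd.DataFrame, species: pd.DataFrame,
                 tolerance: float = 1.0) -> pd.DataFrame:
    """Match observed [M+H]+ MALDI peaks to theoretical species.

    ``peaks`` needs columns ``mz`` and ``intensity``; each peak is assigned
    to the nearest species (on the singly protonated scale) within
    ``tolerance`` Da, otherwise labeled unassigned.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    rows = []
    calc_mz = species["avg_mass"].to_numpy() + PROTON
    for _, peak in peaks.sort_values("mz").iterrows():
        delta = peak["mz"] - calc_mz
        if len(calc_mz):
            best = int(abs(delta).argmin())
            if abs(delta[best]) <= tolerance:
                sp = species.iloc[best]
                rows.append(
                    {
                        "peak_mz": peak["mz"],
                        "intensity": peak["intensity"],
                        "species_name": sp["species_name"],
                        "site": sp["site"],
                        "calc_mass": calc_mz[best],
                        "delta_Da": float(delta[best]),
                        "assigned": 1,
                    }
                )
                continue
        rows.append(
            {
                "peak_mz": peak["mz"], "intensity": peak["intensity"],
                "species_name": "", "site": "", "calc_mass": float("nan"),
                "delta_Da": float("nan"), "assigned": 0,
            }
        )
    return pd.DataFrame(rows)


def load_construct(path: str | Path) -> ConstructSpec:
    """Declarative construct config: name, sequence or variant, sites."""
    cfg = yaml.safe_load(Path(path).read_text())
    sites = cfg.get("sites", DEFAULT_SITES)
    if "full_sequence" in cfg:
        return ConstructSpec(
            name=cfg["name"],
            full_sequence=cfg["full_sequence"],
            numbering_offset=int(cfg.get("numbering_offset", 1)),
            sites={k: int(v) for k, v in sites.items()},
        )
    return c100_his6_construct(
        cfg["name"],
        tmd_replacement={int(k): v for k, v in (cfg.get("tmd_replacement") or {}).items()},
        poly_leu=bool(cfg.get("poly_leu", False)),
        sites={k: int(v) for k, v in sites.items()},
    )
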