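"""Peptide definitions and exchange conditions.

A :class:`PeptideSpec` carries everything the downstream stages need to know
about one analyte: the one-letter sequence (including any solubilizing
Lys-flank tags), the offset that maps 1-based sequence positions onto the
domain numbering used for reporting (e.g. Abeta numbering for the APP C99
transmembrane helix), and the exchange conditions (pH, temperature, cysteine
redox state).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: default assay conditions: pH 5.0, 20.0 degC, reduced cysteines
DEFAULT_PH = 5.0
DEFAULT_TEMPERATURE_K = 293.15


@dataclass(frozen=True)
class PeptideSpec:
    """One peptide with its exchange conditions.

    Parameters
    ----------
    id : str
        Identifier used to join tables across pipeline stages.
    sequence : str
        One-letter amino-acid sequence, 20 standard residues only.
    numbering_offset : int
        Added to the 1-based sequence position to obtain the domain
        (reporting) position.
    pH : float
        Read-direction pH of the exchange buffer (D-to-H exchange in
        protonated solvent, so no pD correction is applied).
    temperature : float
        Temperature in kelvin.
    reduced_cys : bool
        Whether cysteines are reduced (free thiol) rather than in disulfides.
    """

    id: str
    sequence: str
    numbering_offset: int = 0
    pH: float = DEFAULT_PH
    temperature: float = DEFAULT_TEMPERATURE_K
    reduced_cys: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"peptide {self.id!r}: empty sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in STANDARD_AA:
                raise ValueError(
                    f"peptide {self.id!r}: unknown residue {aa!r} at position {i}"
                )
        if self.temperature <= 0:
            raise ValueError(f"peptide {self.id!r}: temperature must be > 0 K")
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError(f"peptide {self.id!r}: pH {self.pH} outside [0, 14]")

    def __len__(self) -> int:
        return len(self.sequence)

    def domain_position(self, position: int) -> int:
        """Map a 1-based sequence position to domain numbering."""
        return position + self.numbering_offset

    def with_conditions(self, **kwargs) -> "PeptideSpec":
        """Return a copy with modified conditions (pH, temperature, ...)."""
        return replace(self, **kwargs)


def read_peptides(fasta: str | Path, conditions: str | Path | None = None) -> list[PeptideSpec]:
    """Read peptides from FASTA plus an optional YAML conditions sidecar.

    The sidecar is a flat mapping with keys ``ph``, ``temperature_c``,
    ``reduced_cys`` and an optional ``offsets`` mapping of record id to
    numbering offset.
    """
    cfg: dict = {}
    if conditions is not None:
        cfg = yaml.safe_load(Path(conditions).read_text()) or {}
    ph = float(cfg.get("ph", DEFAULT_PH))
    temp_k = float(cfg.get("temperature_c", 20.0)) + 273.15
    reduced = bool(cfg.get("reduced_cys", True))
    offsets = cfg.get("offsets", {}) or {}

    peptides = []
    for record in SeqIO.parse(str(fasta), "fasta"):
        peptides.append(
            PeptideSpec(
                id=record.id,
                sequence=str(record.seq).upper(),
                numbering_offset=int(offsets.get(record.id, 0)),
                pH=ph,
                temperature=temp_k,
                reduced_cys=reduced,
            )
        )
    if not peptides:
        raise ValueError(f"no FASTA records found in {fasta}")
    return peptides


def write_fasta(peptides: Iterable[PeptideSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pep in peptides:
            fh.write(f">{pep.id}\n{pep.sequence}\n")


# The C99 transmembrane helix in Abeta numbering (G29..L52) flanked by the
# natural K53-K55 triplet and an artificial N-terminal KKK solubilizing tag,
# the standard design for TMD-peptide exchange assays.
C99_TMD_ABETA_29_52 = "GAIIGLMVGGVVIATVIVITLVML"


def c99_tmd_peptide(pH: float = DEFAULT_PH, temperature: float = DEFAULT_TEMPERATURE_K) -> PeptideSpec:
    """Lys-flanked C99-TMD peptide; sequence position 4 is Abeta position 29."""
    return PeptideSpec(
        id="C99-TMD",
        sequence="KKK" + C99_TMD_ABETA_29_52 + "KKK",
        numbering_offset=25,
        pH=pH,
        temperature=temperature,
    )
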