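"""Peptide bookkeeping for bottom-up HDX-MS.

A peptide observed by MS after proteolysis (or a free synthetic peptide)
exchanges deuterium only at backbone amide positions that survive the
quench/LC step.  The first residue has no amide after digestion (it becomes
a primary amine) and the second residue's label is lost during separation,
so both are excluded from the exchangeable count; proline has no amide
hydrogen at all.  The exchangeable-amide count is therefore

    Q = len(sequence) - 2 - (# prolines at position >= 3)
"""

from __future__ import annotations

from dataclasses import dataclass, field

CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: exclusion reasons used in :class:`ResidueRates` bookkeeping
EXCL_NTERM_1 = "N-terminal-1"
EXCL_NTERM_2 = "N-terminal-2"
EXCL_PROLINE = "proline"


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide with residue numbering in its parent protein.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid sequence (canonical residues only).
    start_residue, end_residue : int
        1-based residue numbers of the first/last residue in the parent
        protein.  For a free synthetic peptide use ``start_residue=1``.
    is_free_peptide : bool
        Synthetic peptide rather than a proteolytic fragment.  Exclusion
        rules are identical in both cases; the flag is bookkeeping only.
    """

    sequence: str
    start_residue: int = 1
    end_residue: int = 0
    is_free_peptide: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if self.end_residue == 0:
            object.__setattr__(
                self, "end_residue", self.start_residue + len(seq) - 1
            )
        if not seq:
            raise ValueError("empty peptide sequence")
        for pos, aa in enumerate(seq, start=1):
            if aa not in CANONICAL_RESIDUES:
                raise ValueError(
                    f"non-canonical residue {aa!r} at position {pos} "
                    f"of {seq!r}"
                )
        if len(seq) != self.end_residue - self.start_residue + 1:
            raise ValueError(
                f"sequence length {len(seq)} inconsistent with residue span "
                f"{self.start_residue}-{self.end_residue}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def exclusion_reason(self, position: int) -> str | None:
        """Why local ``position`` (1-based) is excluded, or None if included."""
        if position == 1:
            return EXCL_NTERM_1
        if position == 2:
            return EXCL_NTERM_2
        if self.sequence[position - 1] == "P":
            return EXCL_PROLINE
        return None

    @property
    def included_positions(self) -> list[int]:
        """1-based local positions carrying a measurable amide deuteron."""
        return [
            i
            for i in range(1, len(self.sequence) + 1)
            if self.exclusion_reason(i) is None
        ]

    @property
    def n_exchangeable(self) -> int:
        """Exchangeable-amide count Q (N-terminal pair and prolines excluded)."""
        return len(self.included_positions)


@dataclass(frozen=True)
class LabelingConditions:
    """Solution conditions of the deuterium labeling reaction.

    ``pD_read`` is the uncorrected pH-meter reading of the D2O labeling
    buffer; the +0.4 glass-electrode correction is applied downstream.
    ``d2o_fraction`` is the deuterium mole fraction after mixing the
    protonated sample with the labeling buffer (a 1:20 mix into 99.9% D2O
    gives 20*0.999/21 ~ 0.95).
    """

    pD_read: float = 7.06
    temperature: float = 296.15
    d2o_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.d2o_fraction <= 1.0:
            raise ValueError(f"d2o_fraction {self.d2o_fraction} not in (0, 1]")
        if self.temperature <= 273.0:
            raise ValueError(f"temperature {self.temperature} K must be > 273 K")

    @property
    def pD(self) -> float:
        """Glass-electrode-corrected pD (= pD_read + 0.4)."""
        return self.pD_read + 0.4


def mixed_d2o_fraction(mix_ratio: float = 20.0, buffer_purity: float = 0.999) -> float:
    """D2O fraction after mixing 1 part protonated sample with ``mix_ratio``
    parts D2O buffer of isotopic purity ``buffer_purity``."""
    if mix_ratio <= 0:
        raise ValueError("mix_ratio must be positive")
    return mix_ratio * buffer_purity / (mix_ratio + 1.0)


#: The five synthetic peptides used as instrument validation standards.
STANDARD_PEPTIDES: dict[str, PeptideSpec] = {
    "bradykinin": PeptideSpec("RPPGFSPFR", is_free_peptide=True),
    "leu-enkephalin": PeptideSpec("YGGFL", is_free_peptide=True),
    "CN-AFP": PeptideSpec(
        "DTASDAAAAAALTAANAAAAAEKTAADAAAAAAATAA", is_free_peptide=True
    ),
    "cTPRH1": PeptideSpec("AEAWYNLGNAYYK", is_free_peptide=True),
    "cTPRS": PeptideSpec("AEAKQNLGNAKQK", is_free_peptide=True),
}
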