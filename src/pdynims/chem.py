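"""Exact-mass calculus for prodynorphin-derived neuropeptides.

Monoisotopic [M+H]+ computation from residue masses, generation of
des-tyrosine metabolites (N-terminal Tyr removal, which abolishes opioid
receptor activation), and tolerance-based annotation of observed m/z values
against a peptide catalog.

The default catalog ships the canonical rat prodynorphin products detected
in substantia nigra — dynorphin A forms, dynorphin B, alpha/beta-neoendorphin,
leu-enkephalin and its C-terminally extended bioconversion products — plus
substance P (amidated) as a non-dynorphin control, and the des-Tyr
metabolites of Dyn A(1-8), aNeo and Dyn B.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "RESIDUE_MONOISOTOPIC",
    "WATER",
    "PROTON",
    "AMIDE_DELTA",
    "TYR_RESIDUE",
    "Peptide",
    "Annotation",
    "monoisotopic_mh",
    "des_tyr",
    "annotate_peaks",
    "default_catalog",
    "load_catalog",
    "write_annotations",
]

#: Monoisotopic residue masses (Da) of the 20 standard amino acids.
RESIDUE_MONOISOTOPIC: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.01056  #: monoisotopic mass of H2O (Da), terminal groups of a free peptide
PROTON = 1.00728  #: monoisotopic proton mass (Da), for [M+H]+
AMIDE_DELTA = -0.98402  #: C-terminal amidation mass shift (OH -> NH2), Da
TYR_RESIDUE = RESIDUE_MONOISOTOPIC["Y"]


@dataclass(frozen=True)
class Peptide:
    """A peptide catalog entry.

    Parameters
    ----------
    name : str
        Display name, e.g. ``"Dyn B"`` or ``"Leu-Enk-Arg"``.
    sequence : str
        One-letter amino-acid string (standard 20-letter alphabet).
    c_term_amide : bool
        True when the C-terminus is amidated (e.g. substance P).
    precursor : str or None
        Parent-peptide name when this peptide is a processing product.
    residue_range : (int, int) or None
        1-based inclusive positions within the precursor sequence.
    note : str
        Free-text flag, used e.g. where a literature-reported integer m/z
        disagrees with the computed monoisotopic [M+H]+.
    """

    name: str
    sequence: str
    c_term_amide: bool = False
    precursor: str | None = None
    residue_range: tuple[int, int] | None = None
    note: str = ""

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        if self.residue_range is not None:
            start, end = self.residue_range
            if end - start + 1 != len(self.sequence):
                raise ValueError(
                    f"{self.name}: residue_range {self.residue_range} does not "
                    f"span {len(self.sequence)} residues"
                )

    @property
    def mh(self) -> float:
        """Monoisotopic [M+H]+ m/z in Da."""
        return monoisotopic_mh(self.sequence, c_term_amide=self.c_term_amide)


@dataclass(frozen=True)
class Annotation:
    """One observed-m/z -> catalog-peptide assignment."""

    observed_mz: float
    peptide_name: str
    theoretical_mz: float
    delta_ppm: float = field(init=False)

    def __post_init__(self) -> None:
        ppm = (self.observed_mz - self.theoretical_mz) / self.theoretical_mz * 1e6
        object.__setattr__(self, "delta_ppm", ppm)


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    for ch in sequence:
        if ch not in RESIDUE_MONOISOTOPIC:
            raise ValueError(f"unknown amino-acid letter {ch!r} in sequence {sequence!r}")


def monoisotopic_mh(sequence: str, c_term_amide: bool = False) -> float:
    """Monoisotopic [M+H]+ m/z of a peptide, in Da.

    Sum of residue monoisotopic masses plus one water (terminal H and OH)
    plus one proton; C-terminal amidation replaces the terminal OH with NH2
    (-0.98402 Da).

    >>> round(monoisotopic_mh("YGGFLR"), 4)
    712.3777
    """
    _validate_sequence(sequence)
    mass = sum(RESIDUE_MONOISOTOPIC[ch] for ch in sequence) + WATER + PROTON
    if c_term_amide:
        mass += AMIDE_DELTA
    return mass


_RANGE_NAME = re.compile(r"^(?P<stem>.*)\(\s*1\s*[-–]\s*(?P<end>\d+)\s*\)$")


def des_tyr(peptide: Peptide) -> Peptide:
    """Return the des-tyrosine metabolite (N-terminal Tyr removed).

    The product is renamed ``<stem>(2-N)``; names already carrying a
    ``(1-N)`` range have the range rewritten, so ``Dyn A(1-8)`` becomes
    ``Dyn A(2-8)`` and ``aNeo`` becomes ``aNeo(2-10)``. The monoisotopic
    mass drops by exactly one tyrosine residue (163.0633 Da).
    """
    seq = peptide.sequence
    if not seq.startswith("Y") or len(seq) < 2:
        raise ValueError(
            f"des-Tyr undefined for {peptide.name!r}: sequence does not start "
            "with an N-terminal tyrosine followed by at least one residue"
        )
    m = _RANGE_NAME.match(peptide.name.strip())
    if m:
        new_name = f"{m.group('stem').rstrip()}(2-{m.group('end')})"
    else:
        new_name = f"{peptide.name}(2-{len(seq)})"
    new_range = None
    if peptide.residue_range is not None:
        start, end = peptide.residue_range
        new_range = (start + 1, end)
    return replace(
        peptide,
        name=new_name,
        sequence=seq[1:],
        precursor=peptide.precursor or peptide.name,
        residue_range=new_range,
    )


def annotate_peaks(
    mz_list: Sequence[float],
    catalog: Sequence[Peptide],
    tolerance: float = 0.3,
    unit: str = "Da",
) -> list[list[Annotation]]:
    """Match observed m/z values to catalog peptides within a tolerance.

    Parameters
    ----------
    mz_list : sequence of float
        Observed singly-protonated m/z values.
    catalog : sequence of Peptide
        Candidate peptides.
    tolerance : float
        Match window, in Da (default 0.3, adequate for unit-resolution TOF
        bins) or ppm depending on ``unit``.
    unit : {"Da", "ppm"}

    Returns
    -------
    list of list of Annotation
        One (possibly empty) list per observed m/z, sorted by \\|delta_ppm\\|
        ascending, ties broken alphabetically by peptide name.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if unit not in ("Da", "ppm"):
        raise ValueError(f"unit must be 'Da' or 'ppm', got {unit!r}")
    if not catalog:
        raise ValueError("catalog must not be empty")
    out: list[list[Annotation]] = []
    for mz in mz_list:
        hits = []
        for pep in catalog:
            theo = pep.mh
            delta = mz - theo
            window = tolerance if unit == "Da" else tolerance * theo / 1e6
            if abs(delta) <= window:
                hits.append(Annotation(observed_mz=mz, peptide_name=pep.name, theoretical_mz=theo))
        hits.sort(key=lambda a: (abs(a.delta_ppm), a.peptide_name))
        out.append(hits)
    return out


def load_catalog(path) -> list[Peptide]:
    """Read a peptide catalog CSV.

    Columns: ``name, sequence, c_term_amide, precursor, range_start,
    range_end, note`` (the last three optional per row).
    """
    peptides = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rng = None
            if row.get("range_start") and row.get("range_end"):
                rng = (int(row["range_start"]), int(row["range_end"]))
            peptides.append(
                Peptide(
                    name=row["name"].strip(),
                    sequence=row["sequence"].strip(),
                    c_term_amide=row.get("c_term_amide", "").strip().lower()
                    in ("1", "true", "yes"),
                    precursor=(row.get("precursor") or "").strip() or None,
                    residue_range=rng,
                    note=(row.get("note") or "").strip(),
                )
            )
    if not peptides:
        raise ValueError(f"catalog file {path} contains no peptides")
    return peptides


def default_catalog() -> list[Peptide]:
    """The packaged rat prodynorphin catalog (plus substance P)."""
    with resources.as_file(
        resources.files("pdynims").joinpath("data/catalog.csv")
    ) as p:
        return load_catalog(p)


def write_annotations(annotations: Iterable[Iterable[Annotation]], path) -> None:
    """Export nested annotation lists as a flat CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["observed_mz", "peptide_name", "theoretical_mz", "delta_ppm"])
        for group in annotations:
            for a in group:
                writer.writerow(
                    [f"{a.observed_mz:.4f}", a.peptide_name, f"{a.theoretical_mz:.4f}", f"{a.delta_ppm:.2f}"]
                )
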