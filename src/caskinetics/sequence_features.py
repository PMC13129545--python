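"""gRNA spacer parsing and nucleotide-composition features.

Cas12a guide RNAs carry a 20-nt spacer whose PAM-proximal prefix (the
"seed", first 8 nt here) dominates early target engagement.  This module
validates spacer sequences, extracts the seed, and computes the base
composition features (purine/pyrimidine and AU/GC partitions, per-base
fractions) that the downstream slowdown analysis consumes.

Fractions are stored exactly as :class:`fractions.Fraction`; equality
checks on composition therefore never rely on float comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import AlphabetError, LengthError

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")
PURINES = frozenset("AG")
PYRIMIDINES_RNA = frozenset("CU")

SPACER_LENGTH = 20
DEFAULT_SEED_LENGTH = 8


def _validate_rna(sequence: str, *, context: str = "sequence") -> str:
    seq = str(sequence)
    if not seq:
        raise AlphabetError(f"{context} is empty")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        hint = ""
        if "T" in bad:
            hint = " (DNA input? use transcribe() to convert T to U explicitly)"
        raise AlphabetError(
            f"{context} contains characters outside {{A,C,G,U}}: {sorted(bad)}{hint}"
        )
    return seq


def transcribe(dna: str) -> str:
    """Convert a DNA string to its RNA equivalent (T -> U).

    Conversion is deliberately explicit: spacer constructors reject ``T``
    so that the provenance (DNA template vs RNA transcript) of every
    sequence entering the analysis is intentional.
    """
    seq = str(dna).upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"DNA input contains invalid characters: {sorted(bad)}")
    return seq.replace("T", "U")


def reverse_transcribe(rna: str) -> str:
    """Convert an RNA string to its DNA equivalent (U -> T)."""
    return _validate_rna(rna).replace("U", "T")


@dataclass(frozen=True)
class SpacerRecord:
    """A named 20-nt gRNA spacer (RNA alphabet) with an 8-nt seed prefix.

    The seed is the 5' end of the spacer, i.e. the PAM-proximal region
    of the protospacer it addresses.
    """

    name: str
    spacer: str

    def __post_init__(self):
        _validate_rna(self.spacer, context=f"spacer {self.name!r}")
        if len(self.spacer) != SPACER_LENGTH:
            raise LengthError(
                f"spacer {self.name!r} has length {len(self.spacer)}, expected {SPACER_LENGTH}"
            )

    @property
    def seed(self) -> str:
        """The default 8-nt PAM-proximal seed prefix."""
        return self.spacer[:DEFAULT_SEED_LENGTH]


def seed_of(record: SpacerRecord, seed_length: int = DEFAULT_SEED_LENGTH) -> str:
    """Return the 5' (PAM-proximal) prefix of the spacer.

    The canonical Cas12a seed is 5-6 nt; analyses here use the first
    8 nt by default, but the length is a parameter.
    """
    if seed_length <= 0:
        raise LengthError(f"seed_length must be positive, got {seed_length}")
    if seed_length > len(record.spacer):
        raise LengthError(
            f"seed_length {seed_length} exceeds spacer length {len(record.spacer)}"
        )
    return record.spacer[:seed_length]


@dataclass(frozen=True)
class CompositionProfile:
    """Exact base counts and fractions for one sequence region."""

    region: str
    length: int
    n_A: int
    n_C: int
    n_G: int
    n_U: int
    purine_count: int = field(init=False)
    pyrimidine_count: int = field(init=False)
    au_count: int = field(init=False)
    gc_count: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "purine_count", self.n_A + self.n_G)
        object.__setattr__(self, "pyrimidine_count", self.n_C + self.n_U)
        object.__setattr__(self, "au_count", self.n_A + self.n_U)
        object.__setattr__(self, "gc_count", self.n_G + self.n_C)

    def _frac(self, count: int) -> Fraction:
        return Fraction(count, self.length)

    @property
    def f_R(self) -> Fraction:
        """Purine fraction (A+G)/length."""
        return self._frac(self.purine_count)

    @property
    def f_Y(self) -> Fraction:
        """Pyrimidine fraction (C+U)/length."""
        return self._frac(self.pyrimidine_count)

    @property
    def f_A(self) -> Fraction:
        return self._frac(self.n_A)

    @property
    def f_C(self) -> Fraction:
        return self._frac(self.n_C)

    @property
    def f_G(self) -> Fraction:
        return self._frac(self.n_G)

    @property
    def f_U(self) -> Fraction:
        return self._frac(self.n_U)

    @property
    def f_AU(self) -> Fraction:
        return self._frac(self.au_count)

    @property
    def f_GC(self) -> Fraction:
        return self._frac(self.gc_count)


def composition_profile(sequence: str, region: str = "custom") -> CompositionProfile:
    """Count bases in an RNA region and derive exact composition fractions."""
    seq = _validate_rna(sequence, context=f"region {region!r}")
    return CompositionProfile(
        region=region,
        length=len(seq),
        n_A=seq.count("A"),
        n_C=seq.count("C"),
        n_G=seq.count("G"),
        n_U=seq.count("U"),
    )


def feature_table(
    records: Iterable[SpacerRecord], seed_length: int = DEFAULT_SEED_LENGTH
) -> pd.DataFrame:
    """One row of composition features per spacer (seed and full spacer).

    Fraction columns are float (for numerics downstream); count columns
    are exact integers and are the ones compared in equality tests.
    """
    rows = []
    for rec in records:
        seed = composition_profile(seed_of(rec, seed_length), region="seed")
        full = composition_profile(rec.spacer, region="full_spacer")
        rows.append(
            {
                "name": rec.name,
                "spacer": rec.spacer,
                "seed": seed_of(rec, seed_length),
                "seed_purine_count": seed.purine_count,
                "seed_pyrimidine_count": seed.pyrimidine_count,
                "seed_au_count": seed.au_count,
                "seed_gc_count": seed.gc_count,
                "seed_f_R": float(seed.f_R),
                "seed_f_U": float(seed.f_U),
                "seed_f_C": float(seed.f_C),
                "seed_f_GC": float(seed.f_GC),
                "spacer_purine_count": full.purine_count,
                "spacer_pyrimidine_count": full.pyrimidine_count,
                "spacer_au_count": full.au_count,
                "spacer_gc_count": full.gc_count,
                "spacer_f_R": float(full.f_R),
                "spacer_f_U": float(full.f_U),
                "spacer_f_C": float(full.f_C),
                "spacer_f_GC": float(full.f_GC),
            }
        )
    columns = [
        "name", "spacer", "seed",
        "seed_purine_count", "seed_pyrimidine_count", "seed_au_count", "seed_gc_count",
        "seed_f_R", "seed_f_U", "seed_f_C", "seed_f_GC",
        "spacer_purine_count", "spacer_pyrimidine_count", "spacer_au_count", "spacer_gc_count",
        "spacer_f_R", "spacer_f_U", "spacer_f_C", "spacer_f_GC",
    ]
    return pd.DataFrame(rows, columns=columns)


def read_spacers_fasta(path: str | Path) -> list[SpacerRecord]:
    """Read spacers from FASTA; the record id carries the gRNA name."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SpacerRecord(name=rec.id, spacer=str(rec.seq).upper()))
    return records


def read_spacers_csv(path: str | Path) -> list[SpacerRecord]:
    """Read spacers from a two-column CSV with header ``name,spacer``."""
    df = pd.read_csv(path)
    if not {"name", "spacer"}.issubset(df.columns):
        raise LengthError("spacer CSV must have columns 'name' and 'spacer'")
    return [SpacerRecord(str(r["name"]), str(r["spacer"]).upper()) for _, r in df.iterrows()]


def write_spacers_fasta(records: Sequence[SpacerRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n{rec.spacer}\n")
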