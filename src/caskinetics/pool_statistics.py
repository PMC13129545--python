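"""Occurrence statistics for PAM and PAM+seed motifs in random pools.

For a random dsDNA pool with an L-nt uniformly random core, the expected
number of Cas12a PAM (5'-TTTV-3') occurrences per molecule is

    N(PAM) = 2 * (L - 4 + 1) * P(PAM),      P(TTTV) = (1/4)^3 * 3/4 = 3/256,

counting both strands and all overlapping windows (linearity of expectation
makes this exact for counts).  Extending a PAM by an m-nt seed-matching
stretch multiplies the probability by (1/4)^m.  Two window-count
conventions are supported for N(PAM + m): the default 2*(L - m + 1), and a
`strict_windows` variant 2*(L - m - 4 + 1) that requires the full
PAM + m-mer window to fit inside the random core.  The default reproduces
the headline pool numbers; the strict count is what a brute-force scanner
over sampled pools measures, and drives the Monte-Carlo cross-checks.

A regex-based scanner over both strands serves as the independent oracle
for these expectations and as the validator for designed backgrounds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import reverse_complement
from scipy.constants import Avogadro

from .errors import AlphabetError, DomainError, LengthError
from .sequence_features import reverse_transcribe

# IUPAC degenerate DNA codes (subset sufficient for PAM patterns).
IUPAC_DNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

UNIFORM_BASE_DISTRIBUTION: Mapping[str, float] = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


@dataclass(frozen=True)
class PamPattern:
    """An IUPAC-degenerate DNA motif, default the Cas12a PAM 5'-TTTV-3'."""

    pattern: str = "TTTV"

    def __post_init__(self):
        if not self.pattern:
            raise LengthError("pattern must be non-empty")
        bad = set(self.pattern) - set(IUPAC_DNA)
        if bad:
            raise AlphabetError(f"invalid IUPAC symbols in pattern: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def allowed_sets(self) -> tuple[frozenset[str], ...]:
        return tuple(IUPAC_DNA[c] for c in self.pattern)

    @property
    def match_probability_per_position(self) -> tuple[float, ...]:
        """Per-position match probability under the uniform base model."""
        return tuple(len(s) / 4.0 for s in self.allowed_sets)

    def regex(self) -> re.Pattern:
        """Overlap-tolerant regex (lookahead capture) for the motif."""
        body = "".join(
            c if len(IUPAC_DNA[c]) == 1 else "[" + "".join(sorted(IUPAC_DNA[c])) + "]"
            for c in self.pattern
        )
        return re.compile(f"(?={body})")


@dataclass(frozen=True)
class RandomPoolModel:
    """Specification of a random-sequence pool.

    L is the randomized core length (dsDNA pools here use 168 nt flanked by
    fixed PAM-free primer sites; ssRNA pools use a fully random 183 nt).
    Expectation formulas cover only the random core: the designed flanks are
    PAM-free by construction (scanning, not expectation, polices that).
    """

    L: int = 168
    strandedness: str = "double"
    flank_5: str = ""
    flank_3: str = ""
    pool_concentration_nM: float | None = None
    base_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(UNIFORM_BASE_DISTRIBUTION)
    )

    def __post_init__(self):
        if self.strandedness not in ("single", "double"):
            raise DomainError(f"strandedness must be 'single' or 'double', got {self.strandedness!r}")
        if self.L < 0:
            raise LengthError(f"L must be non-negative, got {self.L}")
        if self.pool_concentration_nM is not None and self.pool_concentration_nM < 0:
            raise DomainError("pool concentration must be non-negative")

    @property
    def strand_factor(self) -> int:
        return 2 if self.strandedness == "double" else 1


@dataclass(frozen=True)
class SiteHit:
    """One motif occurrence on one strand.

    ``offset`` is the 0-based start of the match on the scanned strand's own
    5'->3' reading; minus-strand hits are reported in minus-strand
    coordinates and are NOT projected back onto the plus strand.
    ``matched_seed_length`` is the number of consecutive bases immediately
    3' of the motif identical to the gRNA seed (transliterated U->T): the
    non-target strand of a protospacer carries the spacer's own sequence.
    """

    strand: str
    offset: int
    matched_seed_length: int = 0


def pam_probability(
    pattern: PamPattern | str,
    base_distribution: Mapping[str, float] | None = None,
) -> float:
    """Probability that a random window matches the motif.

    Product over positions of the allowed-base probability mass; 3/256 for
    TTTV under the uniform model.
    """
    if isinstance(pattern, str):
        pattern = PamPattern(pattern)
    dist = base_distribution or UNIFORM_BASE_DISTRIBUTION
    p = 1.0
    for allowed in pattern.allowed_sets:
        p *= sum(dist[b] for b in allowed)
    return p


def pam_position_count(L: int, pattern_length: int = 4, strandedness: str = "double") -> int:
    """Number of motif windows in an L-nt region: (L - len + 1) per strand."""
    if L < pattern_length:
        raise LengthError(f"L={L} shorter than pattern length {pattern_length}")
    per_strand = L - pattern_length + 1
    return 2 * per_strand if strandedness == "double" else per_strand


def expected_pam_count(pool: RandomPoolModel, pattern: PamPattern | str = PamPattern()) -> float:
    """Expected motif occurrences per molecule: position count x probability.

    Exact for occurrence counts, overlaps included, by linearity of
    expectation.  L=168 dsDNA with TTTV gives 330 * 3/256 = 3.867.
    """
    if isinstance(pattern, str):
        pattern = PamPattern(pattern)
    positions = pam_position_count(pool.L, len(pattern), pool.strandedness)
    return positions * pam_probability(pattern, pool.base_distribution)


def expected_pam_seed_count(
    pool: RandomPoolModel,
    pattern: PamPattern | str = PamPattern(),
    m: int = 8,
    strict_windows: bool = False,
) -> float:
    """Expected motif + m-nt seed-match occurrences per molecule.

    Default window count is strand_factor * (L - m + 1); with
    ``strict_windows`` the motif's own footprint is subtracted,
    strand_factor * (L - m - len(pattern) + 1), so that every counted
    window fits entirely inside the random core (the convention a scanner
    measures).  Either way the expectation decays as (1/4)^m.
    """
    if isinstance(pattern, str):
        pattern = PamPattern(pattern)
    if m < 0:
        raise LengthError(f"seed length m must be non-negative, got {m}")
    if strict_windows:
        per_strand = pool.L - m - len(pattern) + 1
    else:
        per_strand = pool.L - m + 1
    if per_strand < 1:
        raise LengthError(
            f"no window of PAM+{m} fits in L={pool.L} (strict_windows={strict_windows})"
        )
    positions = pool.strand_factor * per_strand
    return positions * pam_probability(pattern, pool.base_distribution) * 0.25**m


def pool_site_concentration(per_molecule_count: float, pool_concentration_nM: float) -> float:
    """Total site concentration in nM: sites per molecule x pool concentration."""
    if per_molecule_count < 0 or pool_concentration_nM < 0:
        raise DomainError("counts and concentrations must be non-negative")
    return per_molecule_count * pool_concentration_nM


def format_concentration(value_nM: float) -> str:
    """Human-readable concentration; values below 1 nM are reported in pM."""
    if value_nM < 0:
        raise DomainError("concentration must be non-negative")
    if 0 < value_nM < 1.0:
        return f"{value_nM * 1e3:.3g} pM"
    return f"{value_nM:.3g} nM"


def distinct_sequence_count(concentration_M: float, volume_L: float) -> float:
    """Expected number of distinct molecules in a sample: N_A * c * V.

    2 uM in 1 uL gives ~1.2e12, i.e. a vanishing fraction of the 4^168
    sequence space of the random core.
    """
    if concentration_M < 0 or volume_L < 0:
        raise DomainError("concentration and volume must be non-negative")
    return Avogadro * concentration_M * volume_L


def _validate_dna(sequence: str) -> str:
    seq = str(sequence).upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise AlphabetError(f"DNA sequence contains invalid characters: {sorted(bad)}")
    return seq


def _seed_run_length(strand_seq: str, start: int, seed_dna: str) -> int:
    """Consecutive seed-identical bases immediately 3' of position start."""
    run = 0
    for i, base in enumerate(seed_dna):
        j = start + i
        if j >= len(strand_seq) or strand_seq[j] != base:
            break
        run += 1
    return run


def scan_motif_sites(
    sequence: str,
    pattern: PamPattern | str = PamPattern(),
    grna_seed: str | None = None,
) -> list[SiteHit]:
    """Brute-force both-strand motif scan; every overlapping match is a hit.

    Each strand is scanned in its own 5'->3' orientation.  If a gRNA seed
    (RNA) is supplied, each hit records how many bases immediately 3' of
    the motif reproduce the seed as DNA — i.e. how far a protospacer's
    non-target strand would match the spacer.
    """
    if isinstance(pattern, str):
        pattern = PamPattern(pattern)
    seq = _validate_dna(sequence)
    seed_dna = reverse_transcribe(grna_seed) if grna_seed else None
    rx = pattern.regex()
    plen = len(pattern)

    hits: list[SiteHit] = []
    for strand, strand_seq in (("+", seq), ("-", reverse_complement(seq))):
        for m in rx.finditer(strand_seq):
            off = m.start()
            run = _seed_run_length(strand_seq, off + plen, seed_dna) if seed_dna else 0
            hits.append(SiteHit(strand=strand, offset=off, matched_seed_length=run))
    return hits


def count_hits(
    sequences: Sequence[str],
    pattern: PamPattern | str = PamPattern(),
    grna_seed: str | None = None,
    min_seed_match: int = 0,
) -> list[int]:
    """Per-sequence hit counts, optionally requiring a minimum seed run.

    Thin convenience over :func:`scan_motif_sites` for Monte-Carlo use.
    """
    counts = []
    for seq in sequences:
        hits = scan_motif_sites(seq, pattern, grna_seed)
        counts.append(sum(1 for h in hits if h.matched_seed_length >= min_seed_match))
    return counts


def write_hits_tsv(hits_by_sequence: Mapping[str, Sequence[SiteHit]], path, pattern_length: int = 4) -> None:
    """BED-like TSV: sequence id, strand, start, end, matched_seed_length."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tstrand\tstart\tend\tmatched_seed_length\n")
        for seq_id, hits in hits_by_sequence.items():
            for h in hits:
                fh.write(
                    f"{seq_id}\t{h.strand}\t{h.offset}\t{h.offset + pattern_length}\t{h.matched_seed_length}\n"
                )
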