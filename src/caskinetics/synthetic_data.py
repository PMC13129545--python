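"""Synthetic inputs emulating the study conditions: random pools, designed
background duplexes, the 17 benchmark spacers, and simulated plates.

Everything the analysis pipeline consumes can be generated here without
downloads:

* semi-random dsDNA pools (fixed PAM-free 20-nt primer flanks around a
  uniformly random 168-nt core, 5'-P1-N168-P2-3'),
* fully random 183-nt ssRNA pools,
* the four designed background variants that dissect the target-search
  pathway (V1: PAM but scrambled seed; V2: full protospacer but no PAM;
  V3: PAM + seed only; V4: eight PAMs, no target complementarity),
* plate-reader datasets with triplicate wells, negative controls, a 1-min
  16-h sampling grid and an explicit noise model.

The noise model (additive Gaussian noise, per-well baseline offsets,
lognormal jitter on the activation rate) is this package's own construct,
chosen to resemble the spread of technical triplicates; it is not derived
from any measured instrument characteristics.  All sampling is driven by a
single seeded generator, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from .errors import DesignError, DomainError
from .kinetics_model import (AssayMix, RateParameters, simulate_model1,
                             simulate_model2)
from .pool_statistics import PamPattern, scan_motif_sites
from .sequence_features import SpacerRecord, reverse_transcribe

DNA_BASES = np.frombuffer(b"ACGT", dtype="S1")
RNA_BASES = np.frombuffer(b"ACGU", dtype="S1")

# Package-designed 20-nt primer flanks, PAM-free on both strands
# (stand-ins for the study's actual primer sites, which are not printed).
DEFAULT_FLANK_5 = "CAGGACGTCCGTACGATGCA"
DEFAULT_FLANK_3 = "GCTAGCACGTGACGGATCAG"

# Benchmark panel of 17 20-nt spacers (gRNA 1-17); the first 8 nt are the seed.
_TABLE1_SPACERS: tuple[tuple[str, str], ...] = (
    ("gRNA 1", "CCACUCCCUAUCAGUGAUAG"),
    ("gRNA 2", "CUCAGGUAUCACUCUAGCAC"),
    ("gRNA 3", "UCCCUUGCCUUCCUCCGUCU"),
    ("gRNA 4", "UGAAAGUGAAUGAUGUGAUG"),
    ("gRNA 5", "CUUACAACCUAUUCCACCCU"),
    ("gRNA 6", "AGCAAAGACACCGAACGAAC"),
    ("gRNA 7", "UUAUUCUUUACAAUAUAAGU"),
    ("gRNA 8", "UAAGAUAUUACAAUAUAAGU"),
    ("gRNA 9", "UAAAUGAUAUAUACUUGAUU"),
    ("gRNA 10", "CCUUCUACUACAAUAUAAGU"),
    ("gRNA 11", "CCUGAUACUACAAUAUAAGU"),
    ("gRNA 12", "ACUGAUAAUACAAUAUAAGU"),
    ("gRNA 13", "UUAUACAUUACAAUAUAAGU"),
    ("gRNA 14", "AAAGAUAAUACAAUAUAAGU"),
    ("gRNA 15", "CAAUAAUGUAAUUAUAAGUU"),
    ("gRNA 16", "AUGUCAUUAAGAUAAUUAUU"),
    ("gRNA 17", "AUGCUAUUAAGAUAAUUAUU"),
)


def table1_fixtures() -> list[SpacerRecord]:
    """The 17 benchmark gRNA spacers as validated records."""
    return [SpacerRecord(name, spacer) for name, spacer in _TABLE1_SPACERS]


# ---------------------------------------------------------------------------
# Random pools

def _random_sequence(rng: np.random.Generator, length: int, bases=DNA_BASES) -> str:
    if length == 0:
        return ""
    idx = rng.integers(0, 4, size=length)
    return bases[idx].tobytes().decode()


def _check_flank_pam_free(flank: str, pattern: PamPattern) -> None:
    if flank and scan_motif_sites(flank, pattern):
        raise DesignError(f"flank {flank!r} contains a PAM on one of its strands")


def generate_random_dsDNA_pool(
    n: int,
    L: int = 168,
    flank_5: str = DEFAULT_FLANK_5,
    flank_3: str = DEFAULT_FLANK_3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[SeqRecord]:
    """Sample n semi-random duplexes 5'-P1-N(L)-P2-3' (plus strand given).

    Flanks are validated to be PAM-free on both strands; the core is
    uniform i.i.d. over {A,C,G,T}.  Deterministic for a fixed seed.
    """
    pattern = PamPattern()
    _check_flank_pam_free(flank_5, pattern)
    _check_flank_pam_free(flank_3, pattern)
    rng = rng or np.random.default_rng(seed)
    records = []
    for i in range(n):
        core = _random_sequence(rng, L)
        records.append(SeqRecord(Seq(flank_5 + core + flank_3),
                                 id=f"dsDNA_{i:05d}", description=f"random core L={L}"))
    return records


def generate_random_ssRNA_pool(
    n: int, L: int = 183, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[SeqRecord]:
    """Sample n fully random single-stranded RNAs of length L (no flanks)."""
    rng = rng or np.random.default_rng(seed)
    return [
        SeqRecord(Seq(_random_sequence(rng, L, RNA_BASES)),
                  id=f"ssRNA_{i:05d}", description=f"random ssRNA L={L}")
        for i in range(n)
    ]


def write_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} {rec.description}\n{rec.seq}\n")


# ---------------------------------------------------------------------------
# Designed background variants (V1-V4)

MAX_DESIGN_ATTEMPTS = 2000
COMPLEMENTARITY_RUN = 4  # forbid shared k-mers of this length with the spacer


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _shares_kmer_with(candidate: str, reference: str, k: int = COMPLEMENTARITY_RUN) -> bool:
    """True if candidate (either strand) shares a k-mer with reference.

    Identity of one candidate strand with the reference implies
    complementarity of the other, so checking both strands for shared
    k-mers covers hybridization-competent runs in either orientation.
    """
    ref = _kmers(reference, k)
    return bool(_kmers(candidate, k) & ref or _kmers(reverse_complement(candidate), k) & ref)


def _random_filler(rng: np.random.Generator, length: int, spacer_dna: str) -> str:
    """Random DNA free of T/A triples (no strand can gain a PAM) and of
    complementarity runs >= COMPLEMENTARITY_RUN to the spacer."""
    for _ in range(MAX_DESIGN_ATTEMPTS):
        cand = _random_sequence(rng, length)
        if "TTT" in cand or "AAA" in cand:
            continue
        if _shares_kmer_with(cand, spacer_dna):
            continue
        return cand
    raise DesignError(f"could not sample a {length}-nt filler for spacer {spacer_dna}")


def _random_pam(rng: np.random.Generator) -> str:
    return "TTT" + "ACG"[rng.integers(0, 3)]


def _validate_design(sequence: str, grna_seed: str, *, expected_hits: int,
                     min_seed_run: int | None = None,
                     max_seed_run: int | None = None, variant: str = "") -> bool:
    hits = scan_motif_sites(sequence, PamPattern(), grna_seed)
    if len(hits) != expected_hits:
        return False
    if min_seed_run is not None and not any(h.matched_seed_length >= min_seed_run for h in hits):
        return False
    if max_seed_run is not None and any(h.matched_seed_length > max_seed_run for h in hits):
        return False
    return True


def generate_designed_background(
    grna: SpacerRecord,
    variant: str,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    seed_length: int = 8,
) -> str:
    """One designed background duplex (plus strand, non-target orientation).

    V1: PAM + scrambled seed (no >=4-nt seed-prefix match) + spacer-matching
        distal 12-mer — probes PAM binding without seed nucleation.
    V2: non-PAM 4-mer + the full 20-nt protospacer — a perfect target that
        cannot be licensed for unwinding.
    V3: PAM + the 8-nt seed match + non-complementary filler — supports
        transient seed nucleation but not full R-loop formation.
    V4: eight PAM sites at fixed 21-nt spacing with non-complementary
        filler — many entry points, no target sequence.

    Every design is verified with the independent motif scanner and
    rejection-sampled until its variant contract holds; spacers whose own
    sequence makes a contract unsatisfiable (e.g. a PAM inside the
    protospacer for V2) raise :class:`DesignError` after a bounded number
    of attempts.
    """
    rng = rng or np.random.default_rng(seed)
    spacer_dna = reverse_transcribe(grna.spacer)
    seed_dna = spacer_dna[:seed_length]
    distal_dna = spacer_dna[seed_length:]
    grna_seed = grna.spacer[:seed_length]

    for _ in range(MAX_DESIGN_ATTEMPTS):
        if variant == "V1":
            scrambled = _random_filler(rng, seed_length, spacer_dna)
            # no accidental seed-prefix match of >= 4 nt next to the PAM
            prefix = 0
            while prefix < seed_length and scrambled[prefix] == seed_dna[prefix]:
                prefix += 1
            if prefix >= COMPLEMENTARITY_RUN:
                continue
            candidate = _random_pam(rng) + scrambled + distal_dna
            ok = _validate_design(candidate, grna_seed, expected_hits=1,
                                  max_seed_run=COMPLEMENTARITY_RUN - 1)
        elif variant == "V2":
            prefix4 = _random_filler(rng, 4, spacer_dna)
            candidate = prefix4 + spacer_dna
            ok = _validate_design(candidate, grna_seed, expected_hits=0)
        elif variant == "V3":
            filler = _random_filler(rng, len(distal_dna), distal_dna)
            candidate = _random_pam(rng) + seed_dna + filler
            ok = _validate_design(candidate, grna_seed, expected_hits=1,
                                  min_seed_run=seed_length)
        elif variant == "V4":
            blocks = [_random_pam(rng) + _random_filler(rng, 17, spacer_dna)
                      for _ in range(8)]
            candidate = "".join(blocks)
            ok = _validate_design(candidate, grna_seed, expected_hits=8,
                                  max_seed_run=COMPLEMENTARITY_RUN - 1)
        else:
            raise DomainError(f"unknown variant {variant!r}; expected V1..V4")
        if ok:
            return candidate
    raise DesignError(
        f"variant {variant} for {grna.name!r}: constraints unsatisfied after "
        f"{MAX_DESIGN_ATTEMPTS} attempts (spacer sequence may preclude the contract)"
    )


# ---------------------------------------------------------------------------
# Simulated plates

@dataclass(frozen=True)
class PlateDesign:
    """Layout of a simulated plate experiment.

    ``conditions`` lists (gRNA name, background label, background
    concentration in nM); each condition gets ``replicates`` sample wells
    plus ``negative_controls`` no-target wells.  Sampling follows the
    plate-reader protocol: one point per minute for 16 h (961 points).
    """

    conditions: tuple = ()
    replicates: int = 3
    negative_controls: int = 3
    duration_h: float = 16.0
    interval_min: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1 or self.negative_controls < 1:
            raise DomainError("every condition needs >= 1 replicate and >= 1 negative control")

    def times_min(self) -> np.ndarray:
        return np.arange(0.0, self.duration_h * 60.0 + 0.5 * self.interval_min,
                         self.interval_min)


@dataclass(frozen=True)
class NoiseModel:
    """Invented plate-noise model (not derived from instrument data).

    additive_sd: i.i.d. Gaussian noise per time point, nM-equivalent.
    baseline_offset_range: per-well constant offset, drawn uniformly.
    rate_jitter_cv: lognormal coefficient of variation applied to the
        activation rate k_ON,T per replicate (mean-one multiplier).
    """

    additive_sd: float = 2.0
    baseline_offset_range: tuple[float, float] = (0.0, 20.0)
    rate_jitter_cv: float = 0.05

    def __post_init__(self):
        if self.additive_sd < 0 or self.rate_jitter_cv < 0:
            raise DomainError("noise parameters must be non-negative")
        if self.baseline_offset_range[0] < 0:
            raise DomainError("baseline offsets must be non-negative")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(additive_sd=0.0, baseline_offset_range=(0.0, 0.0), rate_jitter_cv=0.0)


def _jitter_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    return float(rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma))


def simulate_plate(
    design: PlateDesign,
    rates_by_condition: Mapping[tuple[str, str], RateParameters],
    noise: NoiseModel | None = None,
    mix: AssayMix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a plate: per-well kinetic traces plus a sample sheet.

    Background-free conditions follow Model 1; conditions with a positive
    background concentration follow Model 2 at that concentration.
    Negative-control wells contain no target and report baseline + noise
    only.  Fully deterministic for a fixed design seed.
    """
    noise = noise or NoiseModel()
    base_mix = mix or AssayMix()
    rng = np.random.default_rng(design.seed)
    times = design.times_min()

    plate_rows, sheet_rows = [], []
    well_counter = 0

    def _add_well(values: np.ndarray, grna: str, background: str,
                  conc: float, replicate: int, is_nc: bool) -> None:
        nonlocal well_counter
        well_counter += 1
        well_id = f"W{well_counter:03d}"
        plate_rows.append(pd.DataFrame({
            "time_min": times, "well_id": well_id, "fluorescence": values,
        }))
        sheet_rows.append({
            "well_id": well_id, "grna": grna, "background": background,
            "background_conc_nM": conc, "replicate": replicate,
            "is_negative_control": is_nc,
        })

    for grna, background, conc in design.conditions:
        key = (grna, background)
        if key not in rates_by_condition:
            raise DomainError(f"no rate parameters supplied for condition {key}")
        rates = rates_by_condition[key]
        cond_mix = AssayMix(
            cas_grna_0=base_mix.cas_grna_0, target_0=base_mix.target_0,
            reporter_0=base_mix.reporter_0,
            background_0=conc if background != "none" else 0.0,
        )
        for rep in range(1, design.replicates + 1):
            jitter = _jitter_factor(rng, noise.rate_jitter_cv)
            rep_rates = RateParameters(
                k_on_t=rates.k_on_t * jitter, k2=rates.k2,
                k_on_b=rates.k_on_b, k_off_b=rates.k_off_b,
            )
            if cond_mix.background_0 > 0:
                sim = simulate_model2(rep_rates, cond_mix, times)
            else:
                sim = simulate_model1(rep_rates, cond_mix, times)
            baseline = rng.uniform(*noise.baseline_offset_range)
            values = sim.signal + baseline + rng.normal(0.0, noise.additive_sd, times.size) \
                if noise.additive_sd > 0 else sim.signal + baseline
            _add_well(values, grna, background, conc, rep, False)
        for rep in range(1, design.negative_controls + 1):
            baseline = rng.uniform(*noise.baseline_offset_range)
            values = baseline + rng.normal(0.0, noise.additive_sd, times.size) \
                if noise.additive_sd > 0 else np.full(times.size, baseline)
            _add_well(values, grna, background, conc, rep, True)

    plate = pd.concat(plate_rows, ignore_index=True)
    sheet = pd.DataFrame(sheet_rows)
    return plate, sheet
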