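"""Seed extraction and 3'UTR seed-match scanning for siRNA off-target profiling.

An siRNA guide strand loaded into RISC can behave like a microRNA: short
"seed" subsequences within its 5'-terminal bases 1-8 pair with complementary
sites in the 3'UTRs of unintended transcripts and repress them.  This module
extracts the four canonical seed windows from a guide strand (6mer, two
7mers, 8mer), scans 3'UTR sequence collections for reverse-complement seed
matches, and builds the simulated-siRNA background gene set against which
off-target fold-change shifts are measured.

Conventions
-----------
Guides are RNA (5'->3', alphabet ACGU); UTRs are sense-strand DNA (ACGT,
with N allowed but never matching).  A seed "match" means the UTR contains
the DNA reverse complement of the seed.  Seed windows follow miRNA-field
nomenclature: 8mer = guide bases 1-8, 7mer_a = 1-7, 7mer_b = 2-8,
6mer = 2-7 (configurable to 1-6 or 3-8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

SEED_CLASSES = ("6mer", "7mer_a", "7mer_b", "8mer")

#: start/stop (1-based, inclusive) of each seed window within guide bases 1-8
_SEVEN_EIGHT_WINDOWS = {"7mer_a": (1, 7), "7mer_b": (2, 8), "8mer": (1, 8)}
SIX_MER_WINDOWS = {"1-6": (1, 6), "2-7": (2, 7), "3-8": (3, 8)}

_RNA_ALPHABET = frozenset("ACGU")
_UTR_ALPHABET = frozenset("ACGTN")


class AlphabetError(ValueError):
    """Sequence contains characters outside the permitted alphabet."""


@dataclass(frozen=True)
class GuideStrand:
    """An siRNA guide strand, 5'->3' in RNA alphabet.

    The 5'-terminal bases 1-8 house the seed region.  Therapeutic guides
    are typically 19-23 nt; anything >= 8 nt carries a full seed region.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise ValueError(
                f"guide {self.id!r} is {len(seq)} nt; the seed region "
                "requires at least 8 nt"
            )
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"guide {self.id!r} contains non-RNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SeedSet:
    """The four seed windows of one guide strand (RNA, 5'->3')."""

    guide_id: str
    seeds: dict[str, str]  # seed class -> RNA seed sequence

    def __post_init__(self) -> None:
        if set(self.seeds) != set(SEED_CLASSES):
            raise ValueError(f"expected seed classes {SEED_CLASSES}")

    def dna_sites(self) -> dict[str, str]:
        """DNA reverse complement of each seed: the UTR site sequences."""
        return {cls: seed_to_dna_site(s) for cls, s in self.seeds.items()}


@dataclass(frozen=True)
class UtrRecord:
    """A 3'UTR sequence (sense strand, DNA) keyed by gene id."""

    gene_id: str
    utr_sequence: str

    def __post_init__(self) -> None:
        seq = self.utr_sequence.upper()
        object.__setattr__(self, "utr_sequence", seq)
        if not seq:
            raise ValueError(f"UTR for gene {self.gene_id!r} is empty")
        bad = set(seq) - _UTR_ALPHABET
        if bad:
            raise AlphabetError(
                f"UTR for gene {self.gene_id!r} contains non-DNA "
                f"characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class BackgroundSpec:
    """Parameters of the simulated-siRNA background construction."""

    n_simulated_sirnas: int = 10
    rng_seed: int = 1020
    guide_length: int = 19
    six_mer_window: str = "2-7"

    def __post_init__(self) -> None:
        if self.n_simulated_sirnas < 1:
            raise ValueError("n_simulated_sirnas must be >= 1")
        if self.guide_length < 8:
            raise ValueError("guide_length must be >= 8")


def reverse_complement_dna(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return str(Seq(seq).reverse_complement())


def seed_to_dna_site(seed_rna: str) -> str:
    """DNA sequence a UTR must contain for this RNA seed to match.

    The seed pairs antiparallel with the transcript, so the site is the
    reverse complement with U read as T.
    """
    return str(Seq(seed_rna).back_transcribe().reverse_complement())


def guide_from_target_site(site_dna: str, guide_id: str = "guide") -> GuideStrand:
    """Construct the fully complementary guide strand for a DNA target site."""
    rna = str(Seq(site_dna).reverse_complement().transcribe())
    return GuideStrand(id=guide_id, sequence=rna)


def extract_seeds(guide: GuideStrand, six_mer_window: str = "2-7") -> SeedSet:
    """Extract the 6mer, 7mer_a, 7mer_b, and 8mer seeds from guide bases 1-8.

    Parameters
    ----------
    guide
        Guide strand, >= 8 nt, RNA alphabet (validated on construction).
    six_mer_window
        Which 6-nt window within bases 1-8 defines the 6mer seed:
        "2-7" (default, canonical miRNA seed), "1-6", or "3-8".
    """
    if six_mer_window not in SIX_MER_WINDOWS:
        raise ValueError(
            f"six_mer_window must be one of {sorted(SIX_MER_WINDOWS)}"
        )
    windows = dict(_SEVEN_EIGHT_WINDOWS)
    windows["6mer"] = SIX_MER_WINDOWS[six_mer_window]
    seeds = {
        cls: guide.sequence[start - 1 : stop]
        for cls, (start, stop) in windows.items()
    }
    return SeedSet(guide_id=guide.id, seeds=seeds)


def count_site_occurrences(site: str, utr: str) -> int:
    """Occurrences of ``site`` in ``utr``, overlapping ones counted separately."""
    count = 0
    pos = utr.find(site)
    while pos != -1:
        count += 1
        pos = utr.find(site, pos + 1)
    return count


def scan_utr_matches(
    seeds: SeedSet, utrs: list[UtrRecord] | tuple[UtrRecord, ...]
) -> pd.DataFrame:
    """Scan a 3'UTR collection for reverse-complement matches of each seed.

    Returns a tidy table with columns ``gene_id``, ``seed_class``,
    ``count`` (overlapping occurrences counted separately) and ``hit``
    (count > 0).  Scanning is on the given sense strand only; N positions
    never match.
    """
    if not utrs:
        raise ValueError("UTR collection is empty")
    sites = seeds.dna_sites()
    rows = []
    for rec in utrs:
        for cls in SEED_CLASSES:
            n = count_site_occurrences(sites[cls], rec.utr_sequence)
            rows.append((rec.gene_id, cls, n, n > 0))
    return pd.DataFrame(rows, columns=["gene_id", "seed_class", "count", "hit"])


def hit_genes(matches: pd.DataFrame, seed_class: str) -> set[str]:
    """Gene ids with at least one match for the given seed class."""
    sel = matches[(matches["seed_class"] == seed_class) & matches["hit"]]
    return set(sel["gene_id"])


def draw_simulated_guides(
    spec: BackgroundSpec, exclude: SeedSet | None = None
) -> list[GuideStrand]:
    """Draw uniform-random guide strands for the background construction.

    Guides are i.i.d. uniform over ACGU at ``spec.guide_length``.  Any draw
    whose 6mer seed equals a seed of ``exclude`` (the test siRNA) is
    rejected and redrawn, so the background cannot be contaminated by the
    seed under study.  Deterministic given ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    excluded_seeds = set(exclude.seeds.values()) if exclude is not None else set()
    bases = np.array(list("ACGU"))
    guides: list[GuideStrand] = []
    while len(guides) < spec.n_simulated_sirnas:
        seq = "".join(rng.choice(bases, size=spec.guide_length))
        g = GuideStrand(id=f"sim_{len(guides) + 1}", sequence=seq)
        six = extract_seeds(g, spec.six_mer_window).seeds["6mer"]
        if six in excluded_seeds:
            continue
        guides.append(g)
    return guides


def build_simulated_background(
    spec: BackgroundSpec,
    utrs: list[UtrRecord] | tuple[UtrRecord, ...],
    exclude: SeedSet | None = None,
) -> set[str]:
    """Background gene set: genes with a 6mer match for any simulated siRNA.

    The union over the drawn guides is used (an intersection would usually
    be empty).  Pure function of (spec, utrs, exclude).
    """
    if not utrs:
        raise ValueError("UTR collection is empty")
    background: set[str] = set()
    for g in draw_simulated_guides(spec, exclude):
        seed_set = extract_seeds(g, spec.six_mer_window)
        matches = scan_utr_matches(seed_set, utrs)
        background |= hit_genes(matches, "6mer")
    return background


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(
            f"sequences have unequal lengths ({len(a)} vs {len(b)})"
        )
    return sum(ca != cb for ca, cb in zip(a, b))
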