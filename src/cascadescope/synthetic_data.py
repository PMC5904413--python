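"""Synthetic genomes, planted Cascade target sites, ChIP coverage, and pooled
variant counts with known ground truth.

The generator emulates the three kinds of data the downstream analyses
consume: (a) an i.i.d. random genome carrying planted PAM + protospacer
blocks with a controlled per-position match profile against a chosen spacer;
(b) single-base fragment-pileup coverage with Gaussian-shaped peaks over a
uniform Poisson background, one pileup per bound site with area proportional
to its affinity weight; (c) multinomial read counts over a pooled variant
library under specified per-variant enrichment or depletion factors.  All
randomness flows from one explicit integer seed per operation.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chip_quant import CoverageTrack
from .duplex_model import (
    FLIPPED_POSITIONS,
    TRANSITION,
    TRANSVERSION,
    Spacer,
    TargetSite,
)
from .io import revcomp, write_bed6, BED6_COLUMNS
from .pooled_quant import CountTable

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantSpec:
    """Where and what to plant: one 35-nt PAM+protospacer block.

    ``match_positions`` are the 1-based spacer positions forced to match;
    every other position is forced to mismatch (transversion partner by
    default).  ``offset`` is the 0-based forward-strand start of the block.
    """

    spacer_id: str
    pam: str
    match_positions: frozenset[int]
    contig: str
    offset: int
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "match_positions", frozenset(int(p) for p in self.match_positions)
        )
        if not set(self.pam) <= set("ACGT") or len(self.pam) != 3:
            raise ValueError(f"PAM must be a 3-mer over ACGT, got {self.pam!r}")
        if not self.match_positions <= set(range(1, 33)):
            raise ValueError("match_positions must be within 1..32")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


@dataclass
class PlantedSite:
    """A PlantSpec together with its realized genomic site."""

    spec: PlantSpec
    site: TargetSite


@dataclass
class SimTruth:
    """Ground truth of one simulation: planted sites, weights, abundances."""

    sites: list[PlantedSite] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)
    abundances: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.weights and len(self.weights) != len(self.sites):
            raise ValueError("one affinity weight per planted site required")
        if any(w < 0 for w in self.weights):
            raise ValueError("affinity weights must be nonnegative")
        if self.abundances:
            total = sum(self.abundances.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"pooled abundances must sum to 1 (got {total})")


def make_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random DNA of the given length and GC fraction (deterministic)."""
    if length < 100:
        raise ValueError("genome length must be >= 100")
    if not 0 < gc < 1:
        raise ValueError("gc must be a fraction in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode()


def realize_block(spacer: Spacer, spec: PlantSpec, substitution: str = "transversion") -> str:
    """The 35-nt PAM+protospacer block a spec writes (nontarget-strand sense)."""
    if len(spacer) != 32:
        raise ValueError("planting requires a 32-nt spacer")
    sub = TRANSVERSION if substitution == "transversion" else TRANSITION
    proto = "".join(
        b if (i + 1) in spec.match_positions else sub[b]
        for i, b in enumerate(spacer.sequence)
    )
    return spec.pam + proto


def plant_sites(
    genome: dict[str, str],
    spacer: Spacer,
    specs: list[PlantSpec],
    substitution: str = "transversion",
) -> tuple[dict[str, str], SimTruth]:
    """Write each spec's 35-nt block into the genome; return genome + truth.

    Minus-strand specs are written so that the reverse complement of the
    forward-strand slice reads PAM then protospacer.  Overlapping specs
    raise; mismatching positions are substituted with a base guaranteed to
    differ from the spacer base.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    for spec in specs:
        if spec.contig not in genome:
            raise ValueError(f"unknown contig {spec.contig!r}")
        if spec.offset + 35 > len(genome[spec.contig]):
            raise ValueError(f"spec at {spec.contig}:{spec.offset} runs off the contig")
        for a, b in intervals.get(spec.contig, ()):
            if spec.offset < b and a < spec.offset + 35:
                raise ValueError(
                    f"overlapping plant specs on {spec.contig} at {a} and {spec.offset}"
                )
        intervals.setdefault(spec.contig, []).append((spec.offset, spec.offset + 35))

    out = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    planted: list[PlantedSite] = []
    for spec in specs:
        block = realize_block(spacer, spec, substitution)
        written = block if spec.strand == "+" else revcomp(block)
        out[spec.contig][spec.offset : spec.offset + 35] = written.encode()
        planted.append(
            PlantedSite(
                spec=spec,
                site=TargetSite(
                    contig=spec.contig,
                    start=spec.offset,
                    end=spec.offset + 35,
                    strand=spec.strand,
                    pam=block[:3],
                    protospacer=block[3:],
                ),
            )
        )
    return {name: seq.decode() for name, seq in out.items()}, SimTruth(sites=planted)


def simulate_chip_coverage(
    genome_length: int,
    truth: SimTruth,
    background: float = 1.0,
    fragment_sd: float = 60.0,
    total_reads: int | None = None,
    seed: int = 0,
    contig: str = "chr",
) -> CoverageTrack:
    """Fragment-pileup coverage: Poisson background + Gaussian site pileups.

    Each planted site contributes a Poisson number of fragments with mean
    equal to its affinity weight; each fragment adds a unit-area Gaussian
    kernel (sd = ``fragment_sd``) centred on the site midpoint.  When
    ``total_reads`` is given, background and weights are rescaled jointly so
    the expected fragment total equals it.  The realized fragment count is
    reported on the track for depth normalization.
    """
    if genome_length < 1:
        raise ValueError("genome length must be positive")
    if background < 0 or fragment_sd <= 0:
        raise ValueError("background must be >= 0 and fragment_sd > 0")
    weights = np.asarray(truth.weights, dtype=float) if truth.weights else np.zeros(len(truth.sites))
    if (weights < 0).any():
        raise ValueError("affinity weights must be nonnegative")

    scale = 1.0
    if total_reads is not None:
        expected = background * genome_length + weights.sum()
        if expected <= 0:
            raise ValueError("cannot rescale: expected read total is zero")
        scale = total_reads / expected

    rng = np.random.default_rng(seed)
    coverage = rng.poisson(background * scale, size=genome_length).astype(float)
    n_background = int(coverage.sum())

    positions = np.arange(genome_length)
    n_site_frags = 0
    for planted, w in zip(truth.sites, weights):
        n = rng.poisson(w * scale)
        if n == 0:
            continue
        n_site_frags += int(n)
        mid = (planted.site.start + planted.site.end) // 2
        lo = max(0, int(mid - 5 * fragment_sd))
        hi = min(genome_length, int(mid + 5 * fragment_sd) + 1)
        x = positions[lo:hi]
        kernel = np.exp(-0.5 * ((x - mid) / fragment_sd) ** 2) / (
            fragment_sd * np.sqrt(2 * np.pi)
        )
        coverage[lo:hi] += n * kernel

    return CoverageTrack(
        contig=contig,
        values=coverage,
        total_reads=max(1, n_background + n_site_frags),
    )


def simulate_pool_counts(
    true_abundances: dict[str, float] | pd.Series,
    effect: dict[str, float] | pd.Series | float = 1.0,
    total_reads: int = 100_000,
    seed: int = 0,
    condition: str = "pool",
) -> CountTable:
    """Multinomial read counts over renormalized abundance x effect."""
    abund = pd.Series(true_abundances, dtype=float)
    if abs(abund.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    if np.isscalar(effect):
        eff = pd.Series(float(effect), index=abund.index)
    else:
        eff = pd.Series(effect, dtype=float).reindex(abund.index)
        if eff.isna().any():
            raise ValueError("effect vector must cover every variant")
    if (eff < 0).any():
        raise ValueError("effect factors must be >= 0")
    mass = abund * eff
    if mass.sum() <= 0:
        raise ValueError("all-zero effect vector: no read mass to draw from")
    p = (mass / mass.sum()).to_numpy()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total_reads, p)
    df = pd.DataFrame({condition: counts}, index=abund.index)
    return CountTable(counts=df)


def write_truth(truth: SimTruth, outdir: str | os.PathLike) -> None:
    """Emit BED6 of planted sites, TSVs of weights/abundances, JSON manifest.

    The JSON manifest is the lossless record; BED/TSV are interchange views.
    BED coordinates are 0-based half-open over the 35-nt block.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)

    bed = pd.DataFrame(
        [
            {
                "chrom": p.site.contig,
                "start": p.site.start,
                "end": p.site.end,
                "name": p.spec.spacer_id,
                "score": min(1000, round(1000 * len(p.spec.match_positions) / 32)),
                "strand": p.site.strand,
            }
            for p in truth.sites
        ],
        columns=BED6_COLUMNS,
    )
    write_bed6(bed, os.path.join(outdir, "sites.bed"))

    pd.DataFrame(
        {"site_index": range(len(truth.weights)), "weight": truth.weights}
    ).to_csv(os.path.join(outdir, "weights.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.abundances.items()), columns=["variant", "abundance"]
    ).to_csv(os.path.join(outdir, "abundances.tsv"), sep="\t", index=False)

    manifest = {
        "seed": truth.seed,
        "weights": list(truth.weights),
        "abundances": truth.abundances,
        "sites": [
            {
                "spec": {
                    "spacer_id": p.spec.spacer_id,
                    "pam": p.spec.pam,
                    "match_positions": sorted(p.spec.match_positions),
                    "contig": p.spec.contig,
                    "offset": p.spec.offset,
                    "strand": p.spec.strand,
                },
                "site": {
                    "contig": p.site.contig,
                    "start": p.site.start,
                    "end": p.site.end,
                    "strand": p.site.strand,
                    "pam": p.site.pam,
                    "protospacer": p.site.protospacer,
                },
            }
            for p in truth.sites
        ],
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_truth(outdir: str | os.PathLike) -> SimTruth:
    """Read back a truth directory written by :func:`write_truth`."""
    with open(os.path.join(os.fspath(outdir), "truth.json")) as fh:
        manifest = json.load(fh)
    sites = [
        PlantedSite(
            spec=PlantSpec(
                spacer_id=s["spec"]["spacer_id"],
                pam=s["spec"]["pam"],
                match_positions=frozenset(s["spec"]["match_positions"]),
                contig=s["spec"]["contig"],
                offset=s["spec"]["offset"],
                strand=s["spec"]["strand"],
            ),
            site=TargetSite(**s["site"]),
        )
        for s in manifest["sites"]
    ]
    return SimTruth(
        sites=sites,
        weights=list(manifest["weights"]),
        abundances=dict(manifest["abundances"]),
        seed=manifest["seed"],
    )


def sample_offtarget_specs(
    spacer: Spacer,
    genome_length: int,
    n_sites: int = 60,
    frac_optimal_pam: float = 41 / 60,
    p_match_pos6: float = 0.45,
    mean_ext_optimal: float = 1.2,
    mean_ext_suboptimal: float = 2.2,
    p_background_match: float = 0.25,
    min_spacing: int = 2000,
    margin: int = 1000,
    seed: int = 0,
    contig: str = "chr",
    include_on_target: bool = True,
) -> tuple[list[PlantSpec], list[float]]:
    """A cohort of off-target sites mirroring in vivo binding-site structure.

    Sites carry an intact 5-nt PAM-proximal seed.  A ``frac_optimal_pam``
    share gets the optimal AAG PAM with sparse matches at positions 7-9
    (mean ``mean_ext_optimal`` of 3); the remainder gets a random suboptimal
    PAM compensated by dense 7-9 matches (mean ``mean_ext_suboptimal``).
    Position 6 matches with probability ``p_match_pos6``; PAM-distal
    positions match at the background rate.  Affinity weights are log-uniform
    with the on-target site (full match, planted first when requested)
    dominating.  Returns non-overlapping specs plus one weight per spec.
    """
    rng = np.random.default_rng(seed)
    n_total = n_sites + int(include_on_target)
    span_needed = margin * 2 + n_total * min_spacing
    if span_needed > genome_length:
        raise ValueError("genome too short for the requested site cohort")
    offsets = margin + np.arange(n_total) * min_spacing
    offsets = offsets + rng.integers(0, min_spacing - 40, size=n_total)
    rng.shuffle(offsets)

    suboptimal_pams = [
        "".join(p)
        for p in itertools.product("ACGT", repeat=3)
        if "".join(p) not in ("AAG", "CCG")
    ]

    specs: list[PlantSpec] = []
    weights: list[float] = []
    idx = 0
    if include_on_target:
        specs.append(
            PlantSpec(
                spacer_id=spacer.id,
                pam="AAG",
                match_positions=frozenset(range(1, 33)),
                contig=contig,
                offset=int(offsets[idx]),
                strand="+",
            )
        )
        weights.append(float(10 ** rng.uniform(4.7, 5.0)))
        idx += 1

    n_optimal = int(round(n_sites * frac_optimal_pam))
    for k in range(n_sites):
        optimal = k < n_optimal
        matched = set(range(1, 6))
        if rng.random() < p_match_pos6:
            matched.add(6)
        mean_ext = mean_ext_optimal if optimal else mean_ext_suboptimal
        p_ext = mean_ext / 3.0
        for pos in (7, 8, 9):
            if rng.random() < p_ext:
                matched.add(pos)
        if not optimal and len(matched & {7, 8, 9}) < 2:
            # suboptimal-PAM sites need >= 2 of 7-9 to be detectable at all
            matched |= set(rng.choice([7, 8, 9], size=2, replace=False))
        for pos in range(10, 33):
            if rng.random() < p_background_match:
                matched.add(pos)
        # keep the cohort off-target: never a (near-)full duplex
        nonflipped = [p for p in range(10, 33) if p not in FLIPPED_POSITIONS]
        while all(p in matched for p in nonflipped):
            matched.discard(int(rng.choice(nonflipped)))
        pam = "AAG" if optimal else str(rng.choice(suboptimal_pams))
        strand = "+" if rng.random() < 0.5 else "-"
        specs.append(
            PlantSpec(
                spacer_id=spacer.id,
                pam=pam,
                match_positions=frozenset(matched),
                contig=contig,
                offset=int(offsets[idx]),
                strand=strand,
            )
        )
        # off-target sites bind with < 20% of the on-target ChIP signal;
        # optimal-PAM sites draw mildly higher affinities, so the most
        # enriched bound regions skew toward AAG
        lo, hi = (3.2, 4.0) if optimal else (3.0, 3.8)
        weights.append(float(10 ** rng.uniform(lo, hi)))
        idx += 1
    return specs, weights
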