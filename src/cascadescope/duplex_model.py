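"""crRNA-protospacer duplex model and binding/interference/priming classifier.

The type I-E Cascade complex presents a 32-nt crRNA spacer to double-stranded
DNA targets (protospacers).  Position 1 of the spacer is the PAM-proximal
base; the 3-nt PAM sits immediately 5' of position 1 on the nontarget strand,
and the protospacer is conventionally written as the nontarget-strand DNA, so
spacer and protospacer can be compared base-for-base in the DNA alphabet.
Every sixth spacer position (6, 12, 18, 24, 30) is flipped out of the
crRNA:DNA duplex by the Cas7 backbone and never pairs.

The outcome classifier encodes the minimal rule set consistent with the
in vivo behaviour of a 13-variant protospacer panel: a short PAM-proximal
seed match plus a permissive PAM suffices for (transient) Cascade binding,
stable binding needs an intact duplex through position 18, primed adaptation
through position 24, and interference additionally needs pairing to the
PAM-distal end with an intact seed.  All thresholds are exposed in
:class:`ClassifierConfig`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

from .io import validate_dna

#: Spacer positions excluded from the duplex by Cascade architecture.
FLIPPED_POSITIONS = frozenset({6, 12, 18, 24, 30})

#: Positions of the classical seed region (PAM-proximal, skipping flipped 6).
SEED_POSITIONS = (1, 2, 3, 4, 5, 7, 8)

#: Canonical Chi recombination hotspot, 5'->3'.
CHI_SITE = "GCTGGTGG"

#: Guaranteed-mismatch substitution maps.
TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

PAM_OPTIMAL = "optimal"
PAM_SUBOPTIMAL = "suboptimal"
PAM_NULL = "null"

BINDING_NONE = "none"
BINDING_TRANSIENT = "transient"
BINDING_STABLE = "stable"

_BINDING_RANK = {BINDING_NONE: 0, BINDING_TRANSIENT: 1, BINDING_STABLE: 2}


@dataclass(frozen=True)
class Spacer:
    """A crRNA spacer, 5'->3', position 1 = PAM-proximal base."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_dna(self.sequence, f"spacer {self.id}"))
        if len(self.sequence) < 9:
            raise ValueError(
                f"spacer {self.id}: length {len(self.sequence)} < 9; "
                "seed and extension rules are not evaluable"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CrRNA:
    """A processed crRNA: 5' repeat handle + spacer + 3' repeat hairpin."""

    spacer: Spacer
    handle5: str
    handle3: str

    @property
    def length(self) -> int:
        return len(self.handle5) + len(self.spacer) + len(self.handle3)


def build_crrna(
    spacer: Spacer,
    handle5_len: int = 8,
    handle3_len: int = 21,
    handle5: str | None = None,
    handle3: str | None = None,
) -> CrRNA:
    """Assemble a crRNA from a spacer and repeat-derived handles.

    Default handle lengths (8 nt 5', 21 nt 3') give the canonical 61-nt
    processed crRNA for a 32-nt spacer.  Handle base content is
    user-supplied; when omitted, placeholder ``N`` runs of the requested
    length are used (only lengths matter downstream).
    """
    if handle5_len < 0 or handle3_len < 0:
        raise ValueError("handle lengths must be >= 0")
    h5 = handle5 if handle5 is not None else "N" * handle5_len
    h3 = handle3 if handle3 is not None else "N" * handle3_len
    if len(h5) != handle5_len or len(h3) != handle3_len:
        raise ValueError("explicit handle sequence length disagrees with handle length")
    return CrRNA(spacer=spacer, handle5=h5, handle3=h3)


@dataclass(frozen=True)
class TargetSite:
    """A genomic 3-nt PAM + protospacer block.

    ``start``/``end`` are 0-based half-open forward-strand bounds of the whole
    block; ``pam`` and ``protospacer`` are read 5'->3' on the protospacer-
    bearing (nontarget) strand, PAM immediately 5' of protospacer position 1.
    """

    contig: str
    start: int
    end: int
    strand: str
    pam: str
    protospacer: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pam", validate_dna(self.pam, "pam"))
        object.__setattr__(self, "protospacer", validate_dna(self.protospacer, "protospacer"))
        if len(self.pam) != 3:
            raise ValueError("PAM must be 3 nt")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.end - self.start != len(self.pam) + len(self.protospacer):
            raise ValueError("site bounds do not span PAM + protospacer")


@dataclass(frozen=True)
class MatchProfile:
    """Per-position spacer/protospacer identity with flip-out bookkeeping.

    ``L`` is the PAM-proximal contiguous match length: flipped positions
    never terminate the run, so e.g. a lone mismatch at position 6 leaves
    L = 32.
    """

    matches: tuple[bool, ...]

    @property
    def length(self) -> int:
        return len(self.matches)

    def match_at(self, pos: int) -> bool:
        """Match state at 1-based spacer position ``pos``."""
        return self.matches[pos - 1]

    @property
    def L(self) -> int:
        for pos in range(1, self.length + 1):
            if pos not in FLIPPED_POSITIONS and not self.matches[pos - 1]:
                return pos - 1
        return self.length

    @property
    def seed_matches(self) -> int:
        return sum(self.matches[p - 1] for p in SEED_POSITIONS if p <= self.length)

    @property
    def ext_matches_7_9(self) -> int:
        return sum(self.matches[p - 1] for p in (7, 8, 9) if p <= self.length)

    @property
    def matched_nonflipped(self) -> int:
        return sum(
            self.matches[p - 1]
            for p in range(1, self.length + 1)
            if p not in FLIPPED_POSITIONS
        )

    @property
    def mismatch_blocks(self) -> tuple[tuple[int, int], ...]:
        """Maximal runs of mismatched positions as 1-based inclusive (start, end)."""
        blocks = []
        for is_mm, grp in itertools.groupby(
            range(1, self.length + 1), key=lambda p: not self.matches[p - 1]
        ):
            grp = list(grp)
            if is_mm:
                blocks.append((grp[0], grp[-1]))
        return tuple(blocks)


def match_profile(spacer: Spacer, site: TargetSite) -> MatchProfile:
    """Per-position identity of a spacer against a site's protospacer."""
    if len(spacer) != len(site.protospacer):
        raise ValueError(
            f"spacer length {len(spacer)} != protospacer length {len(site.protospacer)}"
        )
    return MatchProfile(
        matches=tuple(a == b for a, b in zip(spacer.sequence, site.protospacer))
    )


@dataclass(frozen=True)
class PamClassTable:
    """Total map of all 64 PAM 3-mers to {optimal, suboptimal, null}."""

    table: dict[str, str]

    def __post_init__(self) -> None:
        kmers = {"".join(p) for p in itertools.product("ACGT", repeat=3)}
        if set(self.table) != kmers:
            missing = sorted(kmers - set(self.table))[:5]
            raise ValueError(f"PAM table must cover all 64 3-mers (missing e.g. {missing})")
        bad = {v for v in self.table.values()} - {PAM_OPTIMAL, PAM_SUBOPTIMAL, PAM_NULL}
        if bad:
            raise ValueError(f"unknown PAM classes: {sorted(bad)}")

    @classmethod
    def default(cls) -> "PamClassTable":
        """AAG optimal, CCG null, every other 3-mer suboptimal."""
        table = {
            "".join(p): PAM_SUBOPTIMAL for p in itertools.product("ACGT", repeat=3)
        }
        table["AAG"] = PAM_OPTIMAL
        table["CCG"] = PAM_NULL
        return cls(table=table)


def classify_pam(pam: str, table: PamClassTable | None = None) -> str:
    pam = validate_dna(pam, "pam")
    if len(pam) != 3:
        raise ValueError("PAM must be 3 nt")
    table = table if table is not None else PamClassTable.default()
    return table.table[pam]


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds of the outcome classifier.

    Defaults encode the minimal rule set consistent with the 13-variant
    protospacer panel; window bounds are 1-based inclusive spacer positions.
    """

    k_seed: int = 5
    ext_min: int = 2
    stable_window: tuple[int, int] = (4, 18)
    stable_max_mm_1_3: int = 3
    priming_window: tuple[int, int] = (4, 24)
    interference_window: tuple[int, int] = (4, 32)
    interference_max_seed_mm: int = 2
    interference_requires_pos1: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.stable_window, self.priming_window, self.interference_window):
            if not (1 <= lo <= hi <= 32):
                raise ValueError("classifier windows must lie within positions 1..32")
        if self.k_seed < 1:
            raise ValueError("k_seed must be >= 1")
        if min(self.ext_min, self.stable_max_mm_1_3, self.interference_max_seed_mm) < 0:
            raise ValueError("classifier thresholds must be nonnegative")


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class OutcomeCall:
    """Classifier verdict for one site: binding tier, interference, priming.

    Invariant: interference detectable => priming detectable => stable binding.
    """

    binding: str
    interference: str
    priming: str
    trace: tuple[str, ...] = ()

    @property
    def binding_rank(self) -> int:
        return _BINDING_RANK[self.binding]

    @property
    def rank(self) -> tuple[int, int, int]:
        """Componentwise outcome ordering (binding, priming, interference)."""
        return (
            self.binding_rank,
            int(self.priming == "detectable"),
            int(self.interference == "detectable"),
        )


def _nonflipped_window_matched(profile: MatchProfile, window: tuple[int, int]) -> bool:
    lo, hi = window
    return all(
        profile.match_at(p)
        for p in range(lo, hi + 1)
        if p not in FLIPPED_POSITIONS
    )


def classify_outcome(
    profile: MatchProfile,
    pam_class: str,
    cfg: ClassifierConfig = DEFAULT_CONFIG,
) -> OutcomeCall:
    """Binding tier, interference and priming verdict for one match profile.

    Rules, applied in order (flipped positions never count in any window or
    mismatch tally):

    * stable binding: PAM class is not null, all non-flipped positions in
      ``stable_window`` match, and at most ``stable_max_mm_1_3`` mismatches
      in positions 1-3;
    * transient binding: not stable, positions 1..k_seed (non-flipped) all
      match, and the PAM is optimal -- or suboptimal with at least
      ``ext_min`` matches among positions 7-9;
    * priming: stable and all non-flipped positions in ``priming_window``
      match;
    * interference: priming, all non-flipped positions in
      ``interference_window`` match, position 1 matched (if required), and
      at most ``interference_max_seed_mm`` non-flipped mismatches in 1-8.
    """
    if profile.length < 32:
        raise ValueError("classifier requires a profile over >= 32 positions")
    if pam_class not in (PAM_OPTIMAL, PAM_SUBOPTIMAL, PAM_NULL):
        raise ValueError(f"unknown PAM class: {pam_class}")

    trace: list[str] = []

    mm_1_3 = sum(not profile.match_at(p) for p in (1, 2, 3))
    stable = (
        pam_class != PAM_NULL
        and _nonflipped_window_matched(profile, cfg.stable_window)
        and mm_1_3 <= cfg.stable_max_mm_1_3
    )
    if stable:
        trace.append("STABLE")

    seed_ok = all(
        profile.match_at(p)
        for p in range(1, cfg.k_seed + 1)
        if p not in FLIPPED_POSITIONS
    )
    transient = (
        not stable
        and seed_ok
        and (
            pam_class == PAM_OPTIMAL
            or (pam_class == PAM_SUBOPTIMAL and profile.ext_matches_7_9 >= cfg.ext_min)
        )
    )
    if transient:
        trace.append("TRANSIENT_SEED" if pam_class == PAM_OPTIMAL else "TRANSIENT_SEED_EXT")

    priming = stable and _nonflipped_window_matched(profile, cfg.priming_window)
    if priming:
        trace.append("PRIMING_WINDOW")

    seed_mm = sum(
        not profile.match_at(p) for p in range(1, 9) if p not in FLIPPED_POSITIONS
    )
    interference = (
        priming
        and _nonflipped_window_matched(profile, cfg.interference_window)
        and (profile.match_at(1) or not cfg.interference_requires_pos1)
        and seed_mm <= cfg.interference_max_seed_mm
    )
    if interference:
        trace.append("INTERFERENCE_FULL")

    binding = BINDING_STABLE if stable else (BINDING_TRANSIENT if transient else BINDING_NONE)
    return OutcomeCall(
        binding=binding,
        interference="detectable" if interference else "none",
        priming="detectable" if priming else "none",
        trace=tuple(trace),
    )


#: The 13-variant protospacer panel: (label, PAM, mismatch positions, substitution map).
PANEL_DEFINITIONS: tuple[tuple[str, str, frozenset[int], str], ...] = (
    ("i", "AAG", frozenset(), "transversion"),
    ("ii", "CCG", frozenset(), "transversion"),
    ("iii", "ATT", frozenset(), "transversion"),
    ("iv", "AAG", frozenset({1, 2, 3}), "transversion"),
    ("v", "AAG", frozenset({1, 3}), "transversion"),
    ("vi", "AAG", frozenset({1, 3}), "transition"),
    ("vii", "AAG", frozenset({2, 3}), "transversion"),
    ("viii", "AAG", frozenset({2, 3}), "transition"),
    ("ix", "AAG", frozenset(range(25, 33)), "transversion"),
    ("x", "AAG", frozenset(range(19, 33)), "transversion"),
    ("xi", "AAG", frozenset(range(1, 7)), "transversion"),
    ("xii", "AAG", frozenset(range(1, 7)) | frozenset(range(25, 33)), "transversion"),
    ("xiii", "AAG", frozenset(range(7, 25)), "transversion"),
)


def mutate_protospacer(
    spacer: Spacer, mismatch_positions: frozenset[int] | set[int], substitution: str = "transversion"
) -> str:
    """Protospacer equal to the spacer except forced mismatches at given positions."""
    sub = TRANSVERSION if substitution == "transversion" else TRANSITION
    return "".join(
        sub[b] if (i + 1) in mismatch_positions else b
        for i, b in enumerate(spacer.sequence)
    )


def build_variant_panel(spacer: Spacer) -> list[TargetSite]:
    """The 13 protospacer variants (i-xiii) for a 32-nt spacer.

    Variant i is the optimal protospacer (full match, AAG PAM); ii and iii
    swap the PAM for CCG (dead) and ATT (suboptimal); iv-viii carry two or
    three seed mismatches (v/vi and vii/viii share mismatch positions but use
    different substituted bases); ix-xiii carry >= 6-nt mismatch stretches.
    Sites are laid out on a virtual per-variant contig at offset 0.
    """
    if len(spacer) != 32:
        raise ValueError("the variant panel requires a 32-nt spacer")
    panel = []
    for label, pam, mm, sub in PANEL_DEFINITIONS:
        proto = mutate_protospacer(spacer, mm, sub)
        panel.append(
            TargetSite(
                contig=f"variant_{label}",
                start=0,
                end=35,
                strand="+",
                pam=pam,
                protospacer=proto,
            )
        )
    return panel


def classify_panel(
    spacer: Spacer,
    cfg: ClassifierConfig = DEFAULT_CONFIG,
    pam_table: PamClassTable | None = None,
) -> list[tuple[str, TargetSite, MatchProfile, OutcomeCall]]:
    """Build and classify the 13-variant panel; rows (label, site, profile, call)."""
    pam_table = pam_table if pam_table is not None else PamClassTable.default()
    rows = []
    for (label, *_), site in zip(PANEL_DEFINITIONS, build_variant_panel(spacer)):
        prof = match_profile(spacer, site)
        call = classify_outcome(prof, classify_pam(site.pam, pam_table), cfg)
        rows.append((label, site, prof, call))
    return rows


DEFAULT_CHI_WINDOW: tuple[int, ...] = (-1, 1, 2, 3, 4, 5, 6, 7)


def chi_similarity(
    spacer: Spacer, pam: str, window: tuple[int, ...] = DEFAULT_CHI_WINDOW
) -> int:
    """Hamming distance of a PAM/seed-derived 8-mer to the Chi site GCTGGTGG.

    ``window`` selects 8 positions: negative entries index the PAM from its
    3' end (-1 = last PAM base, adjacent to protospacer position 1), positive
    entries are spacer positions.  The default spans the last PAM base and
    spacer positions 1-7.
    """
    pam = validate_dna(pam, "pam")
    if len(pam) != 3:
        raise ValueError("PAM must be 3 nt")
    if len(window) != len(CHI_SITE):
        raise ValueError(f"chi window must select {len(CHI_SITE)} positions")
    kmer = []
    for w in window:
        if w < 0:
            if w < -3:
                raise ValueError("PAM window positions must be -1..-3")
            kmer.append(pam[w])
        elif 1 <= w <= len(spacer):
            kmer.append(spacer.sequence[w - 1])
        else:
            raise ValueError(f"window position {w} outside spacer")
    return sum(a != b for a, b in zip(kmer, CHI_SITE))


def with_config(cfg: ClassifierConfig, **kwargs) -> ClassifierConfig:
    """Convenience: a copy of ``cfg`` with selected thresholds replaced."""
    return replace(cfg, **kwargs)
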