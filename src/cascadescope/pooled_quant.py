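"""Quantification of pooled protospacer-variant experiments.

Reads from a pooled library are assigned to variant references by exact
occurrence of each variant's distinguishing window (the minimal substring
unique to that variant across the library, in either orientation).  From the
resulting count tables the module computes: ChIP enrichment relative to the
optimal variant (input-normalized), interference efficiency relative to the
dead-PAM variant (ratio of counts without vs with the Cas3 nuclease),
single-plasmid transformation-efficiency ratios, and adaptation readouts
(reporter-positive fraction; CRISPR-array expansion units from amplicon
lengths, one unit = 32-nt spacer + 29-nt repeat = 61 bp).

All ratio estimators are invariant to the sequencing depth of any single
condition, and the chosen reference variant maps to exactly 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import revcomp

#: One acquired spacer/repeat unit in the CRISPR array: 32-nt spacer + 29-nt repeat.
EXPANSION_UNIT_BP = 61

#: Relative transformation efficiency measurable floor of the plate assay.
DEFAULT_DETECTION_FLOOR = 3e-5


@dataclass
class VariantLibrary:
    """Variant references plus their automatically derived unique windows.

    A variant's distinguishing window is the shortest (then leftmost)
    substring of its reference that occurs in no other variant's reference
    in either orientation.  Construction fails if any variant has no such
    window (the references would be unresolvable by exact matching).
    """

    references: dict[str, str]
    windows: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.references) < 2:
            raise ValueError("a variant library needs at least 2 variants")
        self.references = {k: v.upper() for k, v in self.references.items()}
        self.windows = {}
        others_cache = {
            vid: [
                (o, revcomp(o))
                for ovid, o in self.references.items()
                if ovid != vid
            ]
            for vid in self.references
        }
        for vid, ref in self.references.items():
            window = self._minimal_unique_window(ref, others_cache[vid])
            if window is None:
                raise ValueError(
                    f"variant {vid!r} has no substring unique within the library"
                )
            self.windows[vid] = window
        if len(set(self.windows.values())) != len(self.windows):
            raise ValueError("distinguishing windows are not pairwise distinct")

    @staticmethod
    def _minimal_unique_window(
        ref: str, others: list[tuple[str, str]]
    ) -> str | None:
        for width in range(1, len(ref) + 1):
            for start in range(len(ref) - width + 1):
                sub = ref[start : start + width]
                if all(sub not in fwd and sub not in rc for fwd, rc in others):
                    return sub
        return None


@dataclass
class CountTable:
    """Reads per variant per condition, with per-condition unassigned counts."""

    counts: pd.DataFrame
    unassigned: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        for cond in self.counts.columns:
            self.unassigned.setdefault(cond, 0)

    def condition(self, name: str) -> pd.Series:
        return self.counts[name]

    def total(self, name: str) -> int:
        return int(self.counts[name].sum()) + int(self.unassigned.get(name, 0))


def assign_reads(
    reads: Iterable[str],
    lib: VariantLibrary,
    condition: str = "reads",
    min_read_length: int = 20,
) -> CountTable:
    """Count reads per variant by exact distinguishing-window occurrence.

    A read increments a variant iff it contains that variant's window
    (searching the read and its reverse complement) and no other variant's
    window; ambiguous (e.g. chimeric) reads go to the unassigned tally.
    """
    counts = {vid: 0 for vid in lib.references}
    unassigned = 0
    items = list(lib.windows.items())
    for read in reads:
        read = read.upper()
        if len(read) < min_read_length:
            raise ValueError(f"read shorter than {min_read_length} nt: {read[:10]}...")
        rc = revcomp(read)
        matched = [vid for vid, win in items if win in read or win in rc]
        if len(matched) == 1:
            counts[matched[0]] += 1
        else:
            unassigned += 1
    df = pd.DataFrame({condition: pd.Series(counts)})
    return CountTable(counts=df, unassigned={condition: unassigned})


def _as_series(counts: "CountTable | pd.Series", condition: str | None = None) -> pd.Series:
    if isinstance(counts, CountTable):
        if condition is None:
            if counts.counts.shape[1] != 1:
                raise ValueError("specify the condition for a multi-condition table")
            condition = counts.counts.columns[0]
        return counts.condition(condition)
    return pd.Series(counts, dtype=float)


def _ratio_of_shares(
    num: pd.Series, den: pd.Series, reference: str
) -> tuple[pd.Series, pd.Series]:
    """(num share / den share) normalized to the reference variant.

    Applies the pseudocount policy: when any non-reference cell is zero, 0.5
    is added to every count in both conditions and the affected variants are
    flagged (their ratios are detection bounds, not point estimates).
    Returns (ratios, zero-flag boolean series).
    """
    num = num.astype(float)
    den = den.reindex(num.index).astype(float)
    if den.isna().any():
        raise ValueError("conditions cover different variant sets")
    if reference not in num.index:
        raise ValueError(f"reference variant {reference!r} not in table")
    if num[reference] == 0 or den[reference] == 0:
        raise ValueError(f"reference variant {reference!r} has a zero count")
    flagged = (num == 0) | (den == 0)
    if flagged.any():
        num = num + 0.5
        den = den + 0.5
    share = (num / num.sum()) / (den / den.sum())
    ratios = share / share[reference]
    return ratios, flagged


def chip_enrichment(
    chip: "CountTable | pd.Series",
    input_counts: "CountTable | pd.Series",
    reference_variant: str = "i",
    chip_condition: str | None = None,
    input_condition: str | None = None,
) -> pd.DataFrame:
    """Per-variant ChIP enrichment relative to the optimal variant.

    e_v = [(chip_v / chip_total) / (input_v / input_total)] divided by the
    same quantity for the reference; the reference maps to exactly 1.0.
    Variants with a zero count are pseudocounted (0.5 everywhere) and
    flagged as bounds.
    """
    chip_s = _as_series(chip, chip_condition)
    input_s = _as_series(input_counts, input_condition)
    ratios, flagged = _ratio_of_shares(chip_s, input_s, reference_variant)
    return pd.DataFrame({"enrichment": ratios, "is_bound": flagged})


def interference_efficiency(
    no_cas3: "CountTable | pd.Series",
    cas3: "CountTable | pd.Series",
    reference_variant: str = "ii",
    no_cas3_condition: str | None = None,
    cas3_condition: str | None = None,
) -> pd.DataFrame:
    """Per-variant relative interference from a pooled +-cas3 experiment.

    i_v = (no-cas3 share / cas3 share), normalized to the dead-PAM reference;
    larger means stronger depletion under Cas3, i.e. stronger interference.
    A zero cas3-condition count means depletion at or below detection: the
    pseudocounted ratio is flagged (read as '>= reported value').
    """
    no_s = _as_series(no_cas3, no_cas3_condition)
    cas_s = _as_series(cas3, cas3_condition)
    ratios, flagged = _ratio_of_shares(no_s, cas_s, reference_variant)
    return pd.DataFrame({"interference": ratios, "is_bound": flagged})


@dataclass(frozen=True)
class TransformationEfficiency:
    """Relative transformation efficiency with limit-of-detection handling."""

    value: float
    below_detection: bool
    detection_floor: float


def transformation_efficiency(
    colonies_cas3: int,
    colonies_vector: int,
    reference_cas3: int,
    reference_vector: int,
    detection_floor: float = DEFAULT_DETECTION_FLOOR,
) -> TransformationEfficiency:
    """(cas3/vector) for a protospacer plasmid over the empty-vector control.

    Zero cas3 transformants are legitimate (complete interference) and
    reported as 0 flagged against the assay's limit of detection; zero
    denominators are errors.
    """
    if min(colonies_cas3, colonies_vector, reference_cas3, reference_vector) < 0:
        raise ValueError("colony counts must be nonnegative")
    if colonies_vector == 0 or reference_vector == 0 or reference_cas3 == 0:
        raise ValueError("denominator colony counts must be > 0")
    value = (colonies_cas3 / colonies_vector) / (reference_cas3 / reference_vector)
    return TransformationEfficiency(
        value=value,
        below_detection=(colonies_cas3 == 0),
        detection_floor=detection_floor,
    )


def positive_fraction(positives: int, total: int) -> float:
    """Fraction of reporter-positive events (e.g. YFP+ cells by cytometry)."""
    if total < 1:
        raise ValueError("need at least one event")
    if not 0 <= positives <= total:
        raise ValueError("positives must lie in [0, total]")
    return positives / total


@dataclass(frozen=True)
class ExpansionCall:
    """Array-expansion readout from one amplicon length."""

    units: int
    residual_bp: int
    is_clean: bool


def expansion_units(
    amplicon_length: int,
    parental_length: int,
    unit: int = EXPANSION_UNIT_BP,
) -> ExpansionCall:
    """Acquired spacer/repeat units from a CRISPR-array amplicon length.

    units = round((observed - parental) / unit); a nonzero residual after
    rounding flags an amplicon inconsistent with whole-unit expansion.
    """
    if amplicon_length < 0 or parental_length < 0:
        raise ValueError("amplicon lengths must be nonnegative")
    delta = amplicon_length - parental_length
    units = round(delta / unit)
    residual = delta - units * unit
    return ExpansionCall(units=units, residual_bp=residual, is_clean=(residual == 0))


def adaptation_metrics(
    positives: int | None = None,
    total: int | None = None,
    amplicon_lengths: Sequence[int] | None = None,
    parental_length: int | None = None,
    unit: int = EXPANSION_UNIT_BP,
) -> dict:
    """Adaptation readouts from per-cell events and/or amplicon lengths."""
    out: dict = {}
    if positives is not None and total is not None:
        out["positive_fraction"] = positive_fraction(positives, total)
    if amplicon_lengths is not None:
        if parental_length is None:
            raise ValueError("parental amplicon length required for expansion calls")
        out["expansions"] = [
            expansion_units(length, parental_length, unit) for length in amplicon_lengths
        ]
    if not out:
        raise ValueError("provide events and/or amplicon lengths")
    return out


def panel_library(
    sites: Sequence,
    flank5: str = "GGATCCTCTAGA",
    flank3: str = "GAATTCAAGCTT",
) -> VariantLibrary:
    """A VariantLibrary from panel TargetSites (PAM+protospacer with flanks)."""
    refs = {
        site.contig.removeprefix("variant_"): flank5 + site.pam + site.protospacer + flank3
        for site in sites
    }
    return VariantLibrary(references=refs)
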