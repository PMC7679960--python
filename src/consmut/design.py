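"""Mutation selection, construct assembly and threshold sweeps.

A construct is the reference sequence with every consensus mutation whose
f(cons)/f(WT) ratio lies *strictly above* a chosen threshold, optionally
restricted to a region mask (typically the transmembrane segments of a
membrane protein).  Sweeping a descending list of thresholds yields a graded
panel of constructs whose mutation loads grow as the threshold drops; loads
are reported as a percent of the full reference length, and constructs are
named ``<prefix>_<percent>`` (e.g. ``xCT_20.2``).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .errors import (
    DuplicateMutationError,
    MaskError,
    NotationError,
    ReferenceMismatchError,
)
from .msa_io import SequenceRecord
from .profile import PositionScore

logger = logging.getLogger(__name__)

_NOTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class RegionMask:
    """Inclusive 1-based residue ranges eligible for mutation.

    Overlapping or adjacent input ranges are merged and sorted on
    construction, so ``ranges`` is always disjoint and ascending.
    """

    ranges: tuple[tuple[int, int], ...]

    @classmethod
    def from_ranges(cls, ranges: list[tuple[int, int]]) -> "RegionMask":
        if not ranges:
            raise MaskError("a region mask needs at least one range")
        for start, end in ranges:
            if start < 1:
                raise MaskError(f"range start {start} < 1")
            if start > end:
                raise MaskError(f"range ({start}, {end}) has start > end")
        merged: list[list[int]] = []
        for start, end in sorted(ranges):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        return cls(ranges=tuple((s, e) for s, e in merged))

    def __contains__(self, residue_number: int) -> bool:
        return any(s <= residue_number <= e for s, e in self.ranges)

    @property
    def max_end(self) -> int:
        return max(e for _, e in self.ranges)

    def total_length(self) -> int:
        return sum(e - s + 1 for s, e in self.ranges)


def read_mask(path: str | Path) -> RegionMask:
    """Read a two-column TSV of 1-based inclusive (start, end) ranges.

    ``#`` starts a comment; blank lines are ignored.  An empty file is an
    error — to mutate the whole sequence, omit the mask entirely.
    """
    ranges: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 2:
                raise MaskError(
                    f"{path} line {lineno}: expected two columns (start, end), "
                    f"got {len(parts)}"
                )
            try:
                start, end = int(parts[0]), int(parts[1])
            except ValueError:
                raise MaskError(
                    f"{path} line {lineno}: non-integer bound in {text!r}"
                ) from None
            if start < 1 or start > end:
                raise MaskError(
                    f"{path} line {lineno}: invalid range ({start}, {end})"
                )
            ranges.append((start, end))
    if not ranges:
        raise MaskError(f"{path}: mask file contains no ranges")
    return RegionMask.from_ranges(ranges)


@dataclass(frozen=True)
class Mutation:
    """One point substitution in reference numbering, e.g. V123L."""

    wt_residue: str
    residue_number: int
    new_residue: str

    def __post_init__(self) -> None:
        if self.wt_residue == self.new_residue:
            raise NotationError(
                f"mutation at {self.residue_number} replaces "
                f"{self.wt_residue} with itself"
            )

    @property
    def notation(self) -> str:
        return f"{self.wt_residue}{self.residue_number}{self.new_residue}"

    @classmethod
    def parse(cls, text: str) -> "Mutation":
        m = _NOTATION_RE.match(text)
        if not m:
            raise NotationError(f"cannot parse mutation notation {text!r}")
        return cls(
            wt_residue=m.group(1),
            residue_number=int(m.group(2)),
            new_residue=m.group(3),
        )


@dataclass(frozen=True)
class ConstructDesign:
    """A designed mutant: threshold, mutation set, sequence, load stats."""

    name: str
    threshold: float
    mutations: tuple[Mutation, ...]
    sequence: str
    mutation_count: int
    mutation_percent: float


def round_percent(count: int, length: int) -> float:
    """Mutation load as a percent of *length*, one decimal, round-half-up."""
    pct = Decimal(100 * count) / Decimal(length)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def select_mutations(
    scores: list[PositionScore],
    threshold: float,
    mask: RegionMask | None = None,
) -> list[Mutation]:
    """All consensus mutations with ratio strictly above *threshold*.

    A position is selected iff its score is defined, its consensus residue
    differs from the wild type, its ratio exceeds the threshold (strict
    inequality, so an exact tie is excluded), and it lies inside the mask
    (whole sequence if no mask).  Undefined ratios are never selected.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if mask is not None and scores:
        ref_length = max(s.residue_number for s in scores)
        if mask.max_end > ref_length:
            raise MaskError(
                f"mask extends to residue {mask.max_end} but the reference "
                f"has only {ref_length} residues"
            )
    selected: list[Mutation] = []
    for score in scores:
        if not score.is_defined:
            continue
        if score.consensus_residue == score.wt_residue:
            continue
        if not score.ratio > threshold:
            continue
        if mask is not None and score.residue_number not in mask:
            continue
        selected.append(
            Mutation(
                wt_residue=score.wt_residue,
                residue_number=score.residue_number,
                new_residue=score.consensus_residue,
            )
        )
    return selected


def build_construct(
    reference: SequenceRecord,
    mutations: list[Mutation],
    name: str,
    threshold: float = math.nan,
) -> ConstructDesign:
    """Apply *mutations* to the ungapped *reference* and report the load."""
    seq = list(reference.ungapped())
    seen: set[int] = set()
    ordered = sorted(mutations, key=lambda m: m.residue_number)
    for mut in ordered:
        if mut.residue_number in seen:
            raise DuplicateMutationError(
                f"two mutations at position {mut.residue_number}"
            )
        seen.add(mut.residue_number)
        if not 1 <= mut.residue_number <= len(seq):
            raise ReferenceMismatchError(
                f"position {mut.residue_number} outside reference "
                f"(length {len(seq)})"
            )
        found = seq[mut.residue_number - 1]
        if found != mut.wt_residue:
            raise ReferenceMismatchError(
                f"position {mut.residue_number}: mutation expects "
                f"{mut.wt_residue}, reference has {found}"
            )
        seq[mut.residue_number - 1] = mut.new_residue
    return ConstructDesign(
        name=name,
        threshold=threshold,
        mutations=tuple(ordered),
        sequence="".join(seq),
        mutation_count=len(ordered),
        mutation_percent=round_percent(len(ordered), len(seq)),
    )


def diff_sequences(reference: SequenceRecord, construct: ConstructDesign) -> list[Mutation]:
    """Recover the mutation list by character-wise diff against the reference."""
    ref_seq = reference.ungapped()
    if len(ref_seq) != len(construct.sequence):
        raise ReferenceMismatchError(
            "construct and reference lengths differ: "
            f"{len(construct.sequence)} vs {len(ref_seq)}"
        )
    return [
        Mutation(wt_residue=a, residue_number=i, new_residue=b)
        for i, (a, b) in enumerate(zip(ref_seq, construct.sequence), start=1)
        if a != b
    ]


def sweep_thresholds(
    scores: list[PositionScore],
    thresholds: list[float],
    mask: RegionMask | None,
    reference: SequenceRecord,
    name_prefix: str,
    name_by_threshold: bool = False,
) -> list[ConstructDesign]:
    """One construct per threshold, sorted by descending threshold.

    Constructs are named ``<prefix>_<mutation_percent>`` (one decimal), or
    ``<prefix>_t<threshold>`` with ``name_by_threshold``.  Duplicate
    thresholds are collapsed with a warning.
    """
    if not thresholds:
        raise ValueError("sweep needs at least one threshold")
    unique = sorted(set(thresholds), reverse=True)
    if len(unique) < len(thresholds):
        logger.warning(
            "duplicate thresholds collapsed: %d given, %d unique",
            len(thresholds),
            len(unique),
        )
    panel: list[ConstructDesign] = []
    for threshold in unique:
        mutations = select_mutations(scores, threshold, mask)
        percent = round_percent(len(mutations), len(reference.ungapped()))
        if name_by_threshold:
            name = f"{name_prefix}_t{threshold:g}"
        else:
            name = f"{name_prefix}_{percent:.1f}"
        panel.append(build_construct(reference, mutations, name, threshold))
    return panel


def write_constructs_fasta(panel: list[ConstructDesign], path: str | Path) -> None:
    """Ungapped FASTA, one record per construct, header = construct name."""
    with open(path, "w") as fh:
        for design in panel:
            fh.write(f">{design.name}\n")
            for start in range(0, len(design.sequence), 60):
                fh.write(design.sequence[start : start + 60] + "\n")


def mutation_table(
    panel: list[ConstructDesign], scores: list[PositionScore]
) -> pd.DataFrame:
    """Per-mutation TSV body: construct, notation, residues, frequencies."""
    by_number = {s.residue_number: s for s in scores}
    rows = []
    for design in panel:
        for mut in design.mutations:
            score = by_number[mut.residue_number]
            rows.append(
                {
                    "construct": design.name,
                    "notation": mut.notation,
                    "residue_number": mut.residue_number,
                    "wt_residue": mut.wt_residue,
                    "new_residue": mut.new_residue,
                    "f_wt": score.f_wt,
                    "f_cons": score.f_cons,
                    "ratio": score.ratio,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "construct",
            "notation",
            "residue_number",
            "wt_residue",
            "new_residue",
            "f_wt",
            "f_cons",
            "ratio",
        ],
    )


def write_mutation_table(
    panel: list[ConstructDesign], scores: list[PositionScore], path: str | Path
) -> None:
    mutation_table(panel, scores).to_csv(path, sep="\t", index=False, float_format="%.6g")
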