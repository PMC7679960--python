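"""Synthetic alignments with exactly known column statistics.

Two generators cover the two kinds of ground truth a test can want:

* :func:`generate_msa` samples rows i.i.d. from per-column residue
  distributions (gap drawn first, then a residue conditional on non-gap), so
  empirical frequencies converge to the specified ones and
  :func:`expected_scores` gives the analytic f(cons)/f(WT) target.
* :func:`msa_from_column_counts` builds an alignment whose column
  compositions are *exact* integer counts — no sampling noise at all —
  which is what a worked example with a prescribed mutation count needs.

:func:`stabilization_demo` uses the second to build a 501-residue
membrane-protein-like scenario: a reference with 12 transmembrane-segment
mask ranges, engineered so that thresholds 3.0 and 2.22 select exactly 71
and 101 consensus mutations (loads 14.2% and 20.2%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .design import RegionMask
from .errors import ConfigError
from .msa_io import AMINO_ACIDS, GAP, MSA, SequenceRecord
from .profile import PositionScore, _consensus_residue

REFERENCE_ID = "REF"


@dataclass(frozen=True)
class ColumnSpec:
    """Residue distribution of one column, plus a gap probability.

    ``distribution`` maps standard amino acids to probabilities summing to 1;
    it is the conditional distribution given the row is not a gap.
    """

    distribution: dict[str, float]
    gap_probability: float = 0.0

    def __post_init__(self) -> None:
        if not self.distribution:
            raise ConfigError("column spec has an empty distribution")
        for aa, p in self.distribution.items():
            if aa not in AMINO_ACIDS:
                raise ConfigError(f"column spec: {aa!r} is not a standard amino acid")
            if p < 0:
                raise ConfigError(f"column spec: negative probability for {aa!r}")
        total = sum(self.distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"column spec probabilities sum to {total!r}, expected 1"
            )
        if not 0 <= self.gap_probability < 1:
            raise ConfigError(
                f"gap_probability must be in [0, 1), got {self.gap_probability}"
            )


@dataclass(frozen=True)
class SyntheticMSAConfig:
    """Everything needed to draw one reproducible alignment.

    ``n_sequences`` is the number of *sampled* homolog rows; if
    ``reference_sequence`` is given it is installed verbatim on top as
    record ``REF``, so the alignment then has ``n_sequences + 1`` rows.
    """

    n_sequences: int
    columns: tuple[ColumnSpec, ...]
    reference_sequence: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ConfigError(f"n_sequences must be >= 2, got {self.n_sequences}")
        if not self.columns:
            raise ConfigError("config needs at least one column spec")
        if (
            self.reference_sequence is not None
            and len(self.reference_sequence) != len(self.columns)
        ):
            raise ConfigError(
                f"reference_sequence length {len(self.reference_sequence)} != "
                f"number of columns {len(self.columns)}"
            )


def generate_msa(config: SyntheticMSAConfig) -> MSA:
    """Draw an alignment; byte-identical for identical config and seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_sequences
    rows = [[""] * len(config.columns) for _ in range(n)]
    for j, spec in enumerate(config.columns):
        residues = list(spec.distribution)
        probs = np.array([spec.distribution[aa] for aa in residues])
        probs = probs / probs.sum()  # guard rounding
        drawn = rng.choice(residues, size=n, p=probs)
        if spec.gap_probability > 0:
            gaps = rng.random(n) < spec.gap_probability
            drawn = np.where(gaps, GAP, drawn)
        for i in range(n):
            rows[i][j] = str(drawn[i])
    width = len(str(n))
    records = [
        SequenceRecord(id=f"seq{i + 1:0{width}d}", residues="".join(row))
        for i, row in enumerate(rows)
    ]
    if config.reference_sequence is not None:
        records.insert(
            0, SequenceRecord(id=REFERENCE_ID, residues=config.reference_sequence)
        )
    return MSA(records=tuple(records))


def expected_scores(config: SyntheticMSAConfig) -> list[PositionScore]:
    """Analytic scores under the specified column distributions.

    The sampling noise and the single reference row are ignored: per column,
    consensus is the arg-max of the specified probabilities (same tie rule
    as the empirical scorer) and the ratio is its probability over the
    wild-type's, ``inf`` when the wild type has probability zero.
    """
    if config.reference_sequence is None:
        raise ConfigError("expected_scores needs a reference_sequence")
    scores: list[PositionScore] = []
    residue_number = 0
    for j, (spec, wt) in enumerate(zip(config.columns, config.reference_sequence)):
        if wt == GAP:
            continue
        residue_number += 1
        if wt not in AMINO_ACIDS:
            scores.append(
                PositionScore(
                    residue_number=residue_number,
                    wt_residue=wt,
                    consensus_residue="",
                    f_wt=math.nan,
                    f_cons=math.nan,
                    ratio=math.nan,
                    gap_fraction=spec.gap_probability,
                )
            )
            continue
        probs = {aa: spec.distribution.get(aa, 0.0) for aa in AMINO_ACIDS}
        consensus = _consensus_residue(probs, wt)
        f_wt = probs[wt]
        f_cons = probs[consensus]
        ratio = 1.0 if consensus == wt else (f_cons / f_wt if f_wt > 0 else math.inf)
        scores.append(
            PositionScore(
                residue_number=residue_number,
                wt_residue=wt,
                consensus_residue=consensus,
                f_wt=f_wt,
                f_cons=f_cons,
                ratio=ratio,
                gap_fraction=spec.gap_probability,
            )
        )
    return scores


def load_config(path: str | Path) -> SyntheticMSAConfig:
    """Read a YAML config.

    Schema::

        n_sequences: 100
        seed: 7
        reference_sequence: MKTL...   # optional
        columns:
          - distribution: {L: 0.6, V: 0.4}
            gap_probability: 0.05
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        raw_columns = doc["columns"]
        columns = tuple(
            ColumnSpec(
                distribution=dict(col["distribution"]),
                gap_probability=float(col.get("gap_probability", 0.0)),
            )
            for col in raw_columns
        )
        return SyntheticMSAConfig(
            n_sequences=int(doc["n_sequences"]),
            columns=columns,
            reference_sequence=doc.get("reference_sequence"),
            seed=int(doc.get("seed", 0)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: malformed config ({exc})") from exc


def msa_from_column_counts(
    column_counts: list[dict[str, int]],
    reference_sequence: str | None = None,
    id_prefix: str = "hom",
) -> MSA:
    """Exact-composition alignment: column *j* contains precisely the
    residues of ``column_counts[j]`` (a residue -> count map; ``-`` allowed
    for gaps).  All columns must sum to the same row count.  Rows are filled
    deterministically (residues in sorted order down each column), and a
    ``REF`` record is prepended when *reference_sequence* is given.
    """
    if not column_counts:
        raise ConfigError("need at least one column")
    totals = {sum(c.values()) for c in column_counts}
    if len(totals) != 1:
        raise ConfigError(f"column counts sum to different row numbers: {totals}")
    n_rows = totals.pop()
    if n_rows < 2:
        raise ConfigError("need at least two rows")
    columns: list[str] = []
    for j, counts in enumerate(column_counts):
        expanded = "".join(
            residue * count for residue, count in sorted(counts.items())
        )
        columns.append(expanded)
    width = len(str(n_rows))
    records = [
        SequenceRecord(
            id=f"{id_prefix}{i + 1:0{width}d}",
            residues="".join(col[i] for col in columns),
        )
        for i in range(n_rows)
    ]
    if reference_sequence is not None:
        if len(reference_sequence) != len(column_counts):
            raise ConfigError(
                "reference_sequence length does not match the column count"
            )
        records.insert(
            0, SequenceRecord(id=REFERENCE_ID, residues=reference_sequence)
        )
    return MSA(records=tuple(records))


def stabilization_demo(
    n_residues: int = 501,
    n_strong: int = 71,
    n_moderate: int = 30,
    n_homologs: int = 10,
) -> tuple[MSA, RegionMask]:
    """A deterministic membrane-protein-like scenario for demos and tests.

    Builds an exact-composition alignment of ``n_homologs`` homologs plus a
    reference over ``n_residues`` columns, with 12 evenly spaced
    transmembrane-segment mask ranges.  Inside the mask, ``n_strong``
    positions carry a unanimous non-wild-type consensus (ratio 10 with the
    reference row counted) and ``n_moderate`` further positions an 8:2
    majority (ratio 8/3 ≈ 2.67); everywhere else the wild type is the
    consensus.  Sweeping thresholds 3.0 and 2.22 therefore selects exactly
    ``n_strong`` and ``n_strong + n_moderate`` mutations — with the defaults,
    71 and 101 of 501 residues, i.e. loads 14.2% and 20.2%.
    """
    reference = "".join(
        AMINO_ACIDS[i % len(AMINO_ACIDS)] for i in range(n_residues)
    )
    # 12 TM-like segments of 25 residues, evenly spaced
    n_segments, seg_len = 12, 25
    if n_residues < n_segments * seg_len:
        raise ConfigError("n_residues too small for the 12-segment mask")
    spacing = n_residues // n_segments
    ranges = [
        (k * spacing + 1, k * spacing + seg_len) for k in range(n_segments)
    ]
    mask = RegionMask.from_ranges(ranges)
    mask_positions = [
        p for start, end in mask.ranges for p in range(start, end + 1)
    ]
    if n_strong + n_moderate > len(mask_positions):
        raise ConfigError("mask too small for the requested mutation counts")
    strong = set(mask_positions[:n_strong])
    moderate = set(mask_positions[n_strong : n_strong + n_moderate])

    def other(aa: str) -> str:
        return AMINO_ACIDS[(AMINO_ACIDS.index(aa) + 1) % len(AMINO_ACIDS)]

    column_counts: list[dict[str, int]] = []
    for pos in range(1, n_residues + 1):
        wt = reference[pos - 1]
        if pos in strong:
            column_counts.append({other(wt): n_homologs})
        elif pos in moderate:
            column_counts.append({other(wt): 8, wt: n_homologs - 8})
        else:
            column_counts.append({wt: n_homologs})
    msa = msa_from_column_counts(column_counts, reference_sequence=reference)
    return msa, mask
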