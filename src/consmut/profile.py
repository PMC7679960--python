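"""Column frequency profiles and the f(cons)/f(WT) position score.

The score at a reference position is the ratio of the frequency of the most
common amino acid in that alignment column (the *consensus*) to the frequency
of the wild-type residue there.  A ratio of 1 means the wild type already is
(or co-ties for) the consensus; large ratios flag positions where the
reference deviates from a strongly conserved majority and a consensus
substitution is expected to stabilize the fold.

Frequencies are computed over amino acids only: gaps and ambiguity codes
(B/Z/X/U/O) count toward ``gap_fraction`` but never toward the residue
distribution.  A gap is absence of evidence, not a 21st residue.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyColumnError, UnknownReferenceError
from .msa_io import AMINO_ACIDS, GAP, MSA, ReferenceMapping

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

WEIGHTING_SCHEMES = ("uniform", "position-based")


@dataclass(frozen=True)
class ProfileOptions:
    """Knobs for profile computation.

    pseudocount:
        Non-negative value added to all 20 residue counts of every non-empty
        column before normalization.  Default 0 (raw frequencies).
    weighting:
        ``uniform`` (default) or ``position-based`` (Henikoff & Henikoff
        sequence weights, damping redundant homologs).
    include_reference:
        Whether the reference row contributes to the counts (default True:
        the reference is one homolog among many).
    """

    pseudocount: float = 0.0
    weighting: str = "uniform"
    include_reference: bool = True

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError(f"pseudocount must be >= 0, got {self.pseudocount}")
        if self.weighting not in WEIGHTING_SCHEMES:
            raise ValueError(
                f"weighting must be one of {WEIGHTING_SCHEMES}, got {self.weighting!r}"
            )


@dataclass(frozen=True)
class ColumnProfile:
    """Weighted residue counts of one alignment column.

    ``counts`` maps each of the 20 standard amino acids to its (weighted,
    pseudocounted) count; ``n_effective`` is their sum.  ``is_empty`` marks
    columns with no observed standard residue at all — those carry zero
    counts (no pseudocount) and must not be scored.
    """

    column: int
    counts: dict[str, float]
    n_effective: float
    gap_fraction: float
    is_empty: bool = False

    def frequencies(self) -> dict[str, float]:
        if self.is_empty:
            raise EmptyColumnError(
                f"column {self.column} has no standard residues; no frequencies"
            )
        return {aa: c / self.n_effective for aa, c in self.counts.items()}


@dataclass(frozen=True)
class PositionScore:
    """f(cons)/f(WT) at one 1-based reference position.

    ``ratio`` is ``math.inf`` when the wild-type residue is absent from the
    column and no pseudocount is applied, and ``math.nan`` (with
    ``consensus_residue`` empty) when the column is all-gap or the wild-type
    residue is an ambiguity code — such positions are never selected.
    """

    residue_number: int
    wt_residue: str
    consensus_residue: str
    f_wt: float
    f_cons: float
    ratio: float
    n_effective: float = math.nan
    gap_fraction: float = math.nan

    @property
    def is_defined(self) -> bool:
        return not math.isnan(self.ratio)


def sequence_weights(msa: MSA, scheme: str = "position-based") -> dict[str, float]:
    """Per-sequence weights, normalized to mean 1.

    ``uniform`` returns all ones.  ``position-based`` implements Henikoff &
    Henikoff (1994): in each column a sequence carrying residue *a* receives
    ``1 / (r * s)`` where *r* is the number of distinct standard residues in
    the column and *s* the number of sequences carrying *a*; gap/ambiguity
    rows contribute nothing at that column.  Redundant sequences thus share
    weight while divergent ones keep it.
    """
    if scheme == "uniform":
        return {rec.id: 1.0 for rec in msa.records}
    if scheme != "position-based":
        raise ValueError(f"unknown weighting scheme {scheme!r}")

    raw = np.zeros(len(msa))
    for col in range(msa.n_columns):
        residues = [rec.residues[col] for rec in msa.records]
        standard = [ch for ch in residues if ch in _AA_INDEX]
        if not standard:
            continue
        r = len(set(standard))
        tallies: dict[str, int] = {}
        for ch in standard:
            tallies[ch] = tallies.get(ch, 0) + 1
        for i, ch in enumerate(residues):
            if ch in _AA_INDEX:
                raw[i] += 1.0 / (r * tallies[ch])
    mean = raw.mean()
    if mean == 0:
        raw[:] = 1.0
        mean = 1.0
    return {rec.id: raw[i] / mean for i, rec in enumerate(msa.records)}


def compute_profiles(
    msa: MSA,
    options: ProfileOptions | None = None,
    ref_id: str | None = None,
) -> list[ColumnProfile]:
    """One :class:`ColumnProfile` per alignment column.

    ``ref_id`` is only needed when ``options.include_reference`` is False, to
    know which row to leave out of the counts.
    """
    options = options or ProfileOptions()
    if not options.include_reference:
        if ref_id is None:
            raise UnknownReferenceError(
                "include_reference=False requires the reference id"
            )
        msa.get(ref_id)  # raises if absent

    if options.weighting == "position-based":
        weights_by_id = sequence_weights(msa, "position-based")
    else:
        weights_by_id = {rec.id: 1.0 for rec in msa.records}

    rows = [
        rec
        for rec in msa.records
        if options.include_reference or rec.id != ref_id
    ]
    weights = np.array([weights_by_id[rec.id] for rec in rows])
    # residue index matrix: 0..19 standard, -1 gap/ambiguity
    idx = np.array(
        [[_AA_INDEX.get(ch, -1) for ch in rec.residues] for rec in rows]
    )

    total_weight = weights.sum()
    profiles: list[ColumnProfile] = []
    for col in range(msa.n_columns):
        column_idx = idx[:, col]
        observed = column_idx >= 0
        counts = np.bincount(
            column_idx[observed], weights=weights[observed], minlength=20
        )
        gap_fraction = float(weights[~observed].sum() / total_weight)
        if not observed.any():
            profiles.append(
                ColumnProfile(
                    column=col,
                    counts={aa: 0.0 for aa in AMINO_ACIDS},
                    n_effective=0.0,
                    gap_fraction=gap_fraction,
                    is_empty=True,
                )
            )
            continue
        counts = counts + options.pseudocount
        profiles.append(
            ColumnProfile(
                column=col,
                counts={aa: float(counts[i]) for i, aa in enumerate(AMINO_ACIDS)},
                n_effective=float(counts.sum()),
                gap_fraction=gap_fraction,
            )
        )
    return profiles


def _consensus_residue(frequencies: dict[str, float], wt: str | None) -> str:
    """Arg-max residue with the conservative tie rule.

    If the wild-type residue ties for the maximum it *is* the consensus
    (ratio 1, never selected); otherwise ties break alphabetically.
    """
    f_max = max(frequencies.values())
    tied = [aa for aa, f in frequencies.items() if f == f_max]
    if wt is not None and wt in tied:
        return wt
    return min(tied)


def score_positions(
    profiles: list[ColumnProfile],
    mapping: ReferenceMapping,
    msa: MSA,
) -> list[PositionScore]:
    """Score every reference position; returns ``ref_length`` scores in order.

    All-gap columns and positions whose wild-type residue is an ambiguity
    code yield an undefined score (``ratio`` NaN) with a logged warning;
    selection skips them.
    """
    if len(profiles) != msa.n_columns:
        raise ValueError(
            f"{len(profiles)} profiles for an alignment of {msa.n_columns} columns"
        )
    ref = msa.get(mapping.ref_id)
    scores: list[PositionScore] = []
    for col in sorted(mapping.column_to_residue):
        residue_number = mapping.column_to_residue[col]
        wt = ref.residues[col]
        if wt == GAP:
            raise RuntimeError(
                f"internal inconsistency: mapping covers gapped column {col}"
            )
        profile = profiles[col]
        if profile.is_empty or wt not in _AA_INDEX:
            reason = "all-gap column" if profile.is_empty else f"ambiguous WT {wt!r}"
            logger.warning(
                "position %d (column %d): %s; score undefined",
                residue_number,
                col,
                reason,
            )
            scores.append(
                PositionScore(
                    residue_number=residue_number,
                    wt_residue=wt,
                    consensus_residue="",
                    f_wt=math.nan,
                    f_cons=math.nan,
                    ratio=math.nan,
                    n_effective=profile.n_effective,
                    gap_fraction=profile.gap_fraction,
                )
            )
            continue
        freqs = profile.frequencies()
        consensus = _consensus_residue(freqs, wt)
        f_wt = freqs[wt]
        f_cons = freqs[consensus]
        ratio = 1.0 if consensus == wt else (f_cons / f_wt if f_wt > 0 else math.inf)
        scores.append(
            PositionScore(
                residue_number=residue_number,
                wt_residue=wt,
                consensus_residue=consensus,
                f_wt=f_wt,
                f_cons=f_cons,
                ratio=ratio,
                n_effective=profile.n_effective,
                gap_fraction=profile.gap_fraction,
            )
        )
    return scores


def skipped_positions(scores: list[PositionScore]) -> list[int]:
    """Residue numbers whose ratio is undefined (never selectable)."""
    return [s.residue_number for s in scores if not s.is_defined]


def scores_table(scores: list[PositionScore]) -> pd.DataFrame:
    """Scores as a DataFrame in the standard column order."""
    return pd.DataFrame(
        {
            "residue_number": [s.residue_number for s in scores],
            "wt_residue": [s.wt_residue for s in scores],
            "consensus_residue": [s.consensus_residue for s in scores],
            "f_wt": [s.f_wt for s in scores],
            "f_cons": [s.f_cons for s in scores],
            "ratio": [s.ratio for s in scores],
            "n_effective": [s.n_effective for s in scores],
            "gap_fraction": [s.gap_fraction for s in scores],
        }
    )


def write_scores_tsv(scores: list[PositionScore], path: str | Path) -> None:
    """Write the score table as TSV; infinite ratios serialize as ``inf``."""
    table = scores_table(scores)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
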