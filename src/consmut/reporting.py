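"""Human- and machine-readable design reports.

The annotated alignment renders the reference and a construct in aligned
60-column blocks with a ``*`` marker track under mutated columns — a
diff-able, terminal-friendly stand-in for a color-highlighted figure.  The
panel report is the TSV summary downstream screening decisions are based on.
All report bodies are byte-deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .design import ConstructDesign
from .errors import EmptyPanelError
from .msa_io import GAP, MSA, ReferenceMapping

BLOCK_WIDTH = 60


@dataclass(frozen=True)
class PanelReport:
    """Summary of a construct panel: per-construct stats plus the reference
    positions whose score was undefined and therefore never selectable."""

    constructs: tuple[tuple[str, float, int, float], ...]  # name, threshold, count, percent
    skipped_positions: tuple[int, ...]


def write_annotated_alignment(
    msa: MSA,
    design: ConstructDesign,
    mapping: ReferenceMapping,
    path: str | Path,
) -> None:
    """Reference vs construct in aligned blocks with a mutation marker line.

    The construct sequence is re-gapped onto the alignment columns via the
    reference mapping; a ``*`` sits under every column whose reference
    residue was mutated.
    """
    reference_row = msa.get(mapping.ref_id).residues
    mutated = {m.residue_number for m in design.mutations}
    construct_row = []
    marker_row = []
    for col in range(msa.n_columns):
        residue_number = mapping.column_to_residue.get(col)
        if residue_number is None:
            construct_row.append(GAP)
            marker_row.append(" ")
        else:
            construct_row.append(design.sequence[residue_number - 1])
            marker_row.append("*" if residue_number in mutated else " ")
    construct_str = "".join(construct_row)
    marker_str = "".join(marker_row)

    label_width = max(len(mapping.ref_id), len(design.name)) + 2
    with open(path, "w") as fh:
        for start in range(0, msa.n_columns, BLOCK_WIDTH):
            end = min(start + BLOCK_WIDTH, msa.n_columns)
            fh.write(
                f"{mapping.ref_id:<{label_width}}{reference_row[start:end]}\n"
            )
            fh.write(f"{design.name:<{label_width}}{construct_str[start:end]}\n")
            fh.write(f"{'':<{label_width}}{marker_str[start:end]}".rstrip() + "\n")
            if end < msa.n_columns:
                fh.write("\n")


def panel_table(panel: list[ConstructDesign]) -> pd.DataFrame:
    rows = [
        {
            "construct": d.name,
            "threshold": d.threshold,
            "mutation_count": d.mutation_count,
            "mutation_percent": d.mutation_percent,
        }
        for d in sorted(panel, key=lambda d: d.threshold, reverse=True)
    ]
    return pd.DataFrame(
        rows, columns=["construct", "threshold", "mutation_count", "mutation_percent"]
    )


def write_panel_report(
    panel: list[ConstructDesign],
    path: str | Path,
    skipped_positions: tuple[int, ...] | list[int] = (),
) -> PanelReport:
    """Write the panel summary TSV and return the in-memory report."""
    if not panel:
        raise EmptyPanelError("cannot report an empty construct panel")
    table = panel_table(panel)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return PanelReport(
        constructs=tuple(
            (row.construct, row.threshold, row.mutation_count, row.mutation_percent)
            for row in table.itertuples(index=False)
        ),
        skipped_positions=tuple(skipped_positions),
    )
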