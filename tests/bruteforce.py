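"""Independent brute-force reference implementations for oracle tests.

Deliberately written as plain nested loops over characters, sharing no code
with the package, so agreement between the two routes is meaningful.
"""

STANDARD = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_scores(rows, ref_id, pseudocount=0.0, include_reference=True):
    """Per-reference-position scores as plain dicts.

    ``rows`` is a list of (id, aligned_sequence) pairs.  Returns one dict per
    non-gap reference position with keys residue_number, wt, consensus,
    f_wt, f_cons, ratio (None when undefined).
    """
    ref_seq = dict(rows)[ref_id]
    out = []
    residue_number = 0
    for col in range(len(ref_seq)):
        wt = ref_seq[col]
        if wt == "-":
            continue
        residue_number += 1
        tally = {}
        any_residue = False
        for rid, seq in rows:
            if not include_reference and rid == ref_id:
                continue
            ch = seq[col]
            if ch in STANDARD:
                tally[ch] = tally.get(ch, 0) + 1
                any_residue = True
        if not any_residue or wt not in STANDARD:
            out.append(
                {
                    "residue_number": residue_number,
                    "wt": wt,
                    "consensus": None,
                    "f_wt": None,
                    "f_cons": None,
                    "ratio": None,
                }
            )
            continue
        counts = {}
        for aa in STANDARD:
            counts[aa] = tally.get(aa, 0) + pseudocount
        total = sum(counts.values())
        best = None
        for aa in STANDARD:  # alphabetical scan -> first max wins
            if best is None or counts[aa] > counts[best]:
                best = aa
        if counts[wt] == counts[best]:
            best = wt
        f_cons = counts[best] / total
        f_wt = counts[wt] / total
        if best == wt:
            ratio = 1.0
        elif f_wt == 0:
            ratio = float("inf")
        else:
            ratio = f_cons / f_wt
        out.append(
            {
                "residue_number": residue_number,
                "wt": wt,
                "consensus": best,
                "f_wt": f_wt,
                "f_cons": f_cons,
                "ratio": ratio,
            }
        )
    return out


def brute_force_select(score_dicts, threshold, mask_ranges=None):
    """Selected positions, by looping over the three conditions."""
    chosen = []
    for s in score_dicts:
        if s["ratio"] is None:
            continue
        if s["consensus"] == s["wt"]:
            continue
        if not s["ratio"] > threshold:
            continue
        if mask_ranges is not None:
            inside = False
            for start, end in mask_ranges:
                if start <= s["residue_number"] <= end:
                    inside = True
            if not inside:
                continue
        chosen.append((s["residue_number"], s["wt"], s["consensus"]))
    return chosen
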