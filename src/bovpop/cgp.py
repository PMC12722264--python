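"""Consistency of gametic phase (CGP) between population pairs.

For every marker pair shared by two populations, each population
contributes a signed LD value ``sqrt(r2) * sign(D)`` — magnitude from the
genotypic correlation, sign from the EM gametic covariance.  The CGP
curve is the Pearson correlation of these signed values across the two
populations, per distance bin (same binning as the LD decay table).
Values near 1 mean marker-QTL phase is shared, the prerequisite for
pooling populations in one genomic evaluation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from bovpop.ld import assign_decay_bin, decay_bin_edges

__all__ = ["signed_root_ld", "cgp_curve"]


def signed_root_ld(pairs: pd.DataFrame) -> pd.DataFrame:
    """Append ``signed_r = sqrt(r2) * sign(D)`` to an LD pair table.

    Pairs with undefined r2 are dropped; ``sign(0) = 0``.
    """
    if "D" not in pairs:
        raise ValueError("pair table lacks the EM D column (run ld_scan with_d=True)")
    out = pairs.loc[np.isfinite(pairs["r2"])].copy()
    out["signed_r"] = np.sqrt(out["r2"].to_numpy()) * np.sign(out["D"].to_numpy())
    return out


def cgp_curve(
    pairs_pop1: pd.DataFrame,
    pairs_pop2: pd.DataFrame,
    min_pairs: int = 50,
) -> pd.DataFrame:
    """Per-bin Pearson correlation of signed root-LD between populations.

    Pair tables must come from :func:`bovpop.ld.ld_scan` on the harmonized
    shared marker set; only marker pairs present (with defined LD) in both
    tables enter a bin's correlation.  Bins with fewer than two shared
    pairs get NaN; bins under ``min_pairs`` are flagged unreliable.
    """
    a = signed_root_ld(pairs_pop1)[["marker_i", "marker_j", "distance_bp", "signed_r"]]
    b = signed_root_ld(pairs_pop2)[["marker_i", "marker_j", "signed_r"]]
    merged = a.merge(
        b, on=["marker_i", "marker_j"], how="inner", suffixes=("_1", "_2")
    )
    idx = assign_decay_bin(merged["distance_bp"].to_numpy()) if len(merged) else np.array([], int)
    edges = decay_bin_edges()
    rows = []
    for bin_id in range(len(edges) - 1):
        sel = merged.loc[idx == bin_id]
        n = len(sel)
        if n >= 2 and sel["signed_r_1"].std() > 0 and sel["signed_r_2"].std() > 0:
            corr = float(np.corrcoef(sel["signed_r_1"], sel["signed_r_2"])[0, 1])
        else:
            corr = np.nan
        rows.append(
            {
                "bin_low_bp": int(edges[bin_id]),
                "bin_high_bp": int(edges[bin_id + 1]),
                "correlation": corr,
                "n_shared_pairs": n,
                "reliable": bool(n >= min_pairs),
            }
        )
    return pd.DataFrame(rows)
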