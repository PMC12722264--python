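"""Marker windows, feature overlap, and QTL-category enrichment.

Candidate markers (significant GPSM hits or ROH-island members) are
expanded to +/-100-kb windows, merged, and intersected with
user-supplied gene or QTL interval tables (1-based inclusive
coordinates, GFF3 or TSV).  Over-representation of QTL categories among
the hits is tested with the upper-tail hypergeometric distribution and
Benjamini-Hochberg FDR adjustment.  Annotation sources are always local
files: results depend on the database version, so no live lookups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "windows_from_markers",
    "overlap_features",
    "qtl_enrichment",
    "read_feature_table",
]


def windows_from_markers(
    markers: pd.DataFrame, flank_bp: int = 100_000
) -> pd.DataFrame:
    """Merged +/-flank windows around marker positions, clipped at 1.

    ``markers`` needs ``chromosome`` and ``position_bp`` columns; the
    result has one row per merged interval (1-based inclusive) with a
    ``window_id`` and the member marker ids when available.
    """
    rows = []
    for c, grp in markers.groupby("chromosome", observed=True, sort=False):
        grp = grp.sort_values("position_bp")
        starts = np.maximum(1, grp["position_bp"].to_numpy(dtype=np.int64) - flank_bp)
        ends = grp["position_bp"].to_numpy(dtype=np.int64) + flank_bp
        ids = (
            grp["marker_id"].astype(str).to_numpy()
            if "marker_id" in grp
            else np.array([f"pos{p}" for p in grp["position_bp"]])
        )
        cur_s, cur_e, cur_ids = None, None, []
        for s, e, mid in zip(starts, ends, ids):
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    rows.append((str(c), cur_s, cur_e, ",".join(cur_ids)))
                cur_s, cur_e, cur_ids = int(s), int(e), [mid]
            else:
                cur_e = max(cur_e, int(e))
                cur_ids.append(mid)
        if cur_e is not None:
            rows.append((str(c), cur_s, cur_e, ",".join(cur_ids)))
    out = pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp", "marker_ids"])
    out.insert(0, "window_id", [f"w{i + 1}" for i in range(len(out))])
    return out


def overlap_features(windows: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Features overlapping any window by at least 1 bp (1-based inclusive)."""
    if (features["start_bp"] > features["end_bp"]).any():
        raise ValueError("feature intervals must satisfy start <= end")
    hits = []
    for c, wgrp in windows.groupby("chromosome", observed=True, sort=False):
        fgrp = features[features["chromosome"].astype(str) == str(c)]
        if fgrp.empty:
            continue
        fs = fgrp["start_bp"].to_numpy(dtype=np.int64)
        fe = fgrp["end_bp"].to_numpy(dtype=np.int64)
        for _, w in wgrp.iterrows():
            mask = (fs <= w["end_bp"]) & (fe >= w["start_bp"])
            if mask.any():
                sub = fgrp.loc[mask].copy()
                sub.insert(0, "window_id", w["window_id"])
                hits.append(sub)
    if not hits:
        return pd.DataFrame(
            columns=["window_id", *features.columns.tolist()]
        )
    return pd.concat(hits, ignore_index=True)


def qtl_enrichment(
    hit_categories: pd.Series | list,
    background_categories: pd.Series | list,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per category with BH adjustment.

    For each category with K members in a background of N, observing k
    among the n hits has p = P[X >= k], X ~ Hypergeometric(N, K, n).
    Categories present in the hits but absent from the background raise
    an error (hits must be drawn from the background universe).
    """
    hits = pd.Series(list(hit_categories), dtype=object)
    bg = pd.Series(list(background_categories), dtype=object)
    n, N = len(hits), len(bg)
    bg_counts = bg.value_counts()
    missing = set(hits.unique()) - set(bg_counts.index)
    if missing:
        raise ValueError(f"categories absent from background: {sorted(missing)}")
    rows = []
    for cat, K in bg_counts.items():
        k = int((hits == cat).sum())
        p = float(hypergeom.sf(k - 1, N, int(K), n))
        rows.append(
            {
                "category": cat,
                "hits_in_selection": k,
                "hits_in_background": int(K),
                "selection_size": n,
                "background_size": N,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["fdr_adjusted_p"] = pd.Series(dtype=float)
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def read_feature_table(path) -> pd.DataFrame:
    """Read gene/QTL intervals from GFF3 or a TSV with named columns.

    TSVs need ``feature_id, chromosome, start_bp, end_bp`` and optional
    ``category``; GFF3 rows use the ID attribute (or a running index) as
    feature_id and the source column as category.
    """
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or (first.split("\t")[2:3] and not first.startswith("feature_id")):
        try:
            return _read_gff3(path)
        except Exception:
            pass
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"feature_id", "chromosome", "start_bp", "end_bp"}
    if not required <= set(df.columns):
        raise ValueError(f"feature TSV must have columns {sorted(required)}")
    if "category" not in df:
        df["category"] = "feature"
    return df


def _read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "feature_id": attrs.get("ID", f"feature{i}"),
                    "chromosome": parts[0],
                    "start_bp": int(parts[3]),
                    "end_bp": int(parts[4]),
                    "category": parts[2],
                }
            )
    if not rows:
        raise ValueError(f"no GFF3 feature rows in {path}")
    return pd.DataFrame(rows)
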