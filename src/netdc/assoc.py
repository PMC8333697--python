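"""Cluster-mean extraction and clinical correlation.

Correlations are run on the patient group only by default, at an
uncorrected p < 0.05; an optional Benjamini-Hochberg correction across
clinical variables is available (off by default, and documented as a
deviation from the mirrored analysis when enabled).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError


def extract_cluster_means(maps, labels: np.ndarray, table: pd.DataFrame | None = None,
                          cluster_ids=None) -> pd.DataFrame:
    """Per-subject unweighted mean map value over each cluster's voxels.

    Returns one row per subject with columns ``cluster_<id>``; phenotype
    columns are joined when ``table`` is given.
    """
    labels = np.asarray(labels)
    if cluster_ids is None:
        cluster_ids = [int(c) for c in np.unique(labels[labels > 0])]
    if not cluster_ids:
        raise InputError("no clusters to extract")
    cols = {}
    for cid in cluster_ids:
        where = labels == cid
        if not where.any():
            raise InputError(f"cluster id {cid} is empty")
        vals = []
        for m in maps:
            if m.grid_shape != labels.shape:
                raise InputError("map grid does not match cluster map")
            vals.append(float(np.nanmean(m.data[where])))
        cols[f"cluster_{cid}"] = vals
    out = pd.DataFrame(cols)
    if table is not None:
        if len(table) != len(maps):
            raise InputError("phenotype table length does not match map list")
        out = pd.concat([table.reset_index(drop=True), out], axis=1)
    return out


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p from t = r*sqrt((n-2)/(1-r^2)), df = n-2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1D vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InputError(f"correlation needs n >= 3, got n = {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise InputError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlate_clusters(roi_table: pd.DataFrame, clinical_vars=("SLEDAI", "MoCA", "BDI"),
                       *, patient_only: bool = True,
                       bh_correction: bool = False) -> pd.DataFrame:
    """Correlate every ``cluster_*`` column with every clinical variable."""
    tab = roi_table
    if patient_only:
        tab = tab[tab["group"] == "patient"]
    cluster_cols = [c for c in tab.columns if c.startswith("cluster_")]
    if not cluster_cols:
        raise InputError("roi_table has no cluster_* columns")
    rows = []
    for cc in cluster_cols:
        for var in clinical_vars:
            if var not in tab.columns:
                continue
            x = np.asarray(tab[cc], dtype=float)
            y = np.asarray(tab[var], dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            if keep.sum() < 3:
                continue
            r, p = pearson_correlation(x[keep], y[keep])
            rows.append({"cluster": cc, "variable": var, "n": int(keep.sum()),
                         "r": r, "p": p})
    out = pd.DataFrame(rows, columns=["cluster", "variable", "n", "r", "p"])
    if bh_correction and len(out):
        _, p_adj, _, _ = multipletests(out["p"], method="fdr_bh")
        out["p_fdr"] = p_adj
    return out
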