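"""Surrogate-null term-enrichment decoding.

Given the significant ROIs partitioned by RSN and a ROI -> term table,
each term's observed count (number of significant ROIs carrying it) is
compared against equal-size sets of surrogate ROIs drawn uniformly
without replacement from a configurable pool (whole atlas by default).
z-scores are converted to one-sided upper-tail normal p-values and
BH-FDR corrected across terms within each RSN.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd
from scipy.stats import norm

from .connectivity import Atlas
from .errors import InputError
from .stats import bh_fdr

TermTable = dict[int, list[str]]


def validate_term_table(table: TermTable, atlas: Atlas) -> None:
    atlas_rois = set(atlas.roi_ids)
    for roi, terms in table.items():
        if roi not in atlas_rois:
            raise InputError(f"term table ROI {roi} not in atlas")
        for t in terms:
            if not isinstance(t, str) or not t:
                raise InputError(f"ROI {roi} carries an empty/non-string term")


def term_counts(rois, table: TermTable) -> Counter:
    """ROI-level presence counts: how many of the given ROIs carry each term."""
    counts: Counter = Counter()
    for roi in rois:
        if roi not in table:
            raise InputError(f"unknown ROI in term table: {roi}")
        counts.update(set(table[roi]))
    return counts


def _surrogate_pool(atlas: Atlas, rsn: str, pool: str) -> list[int]:
    if pool == "atlas":
        return list(atlas.roi_ids)
    if pool == "rsn":
        return atlas.rois_in_rsn(rsn)
    raise InputError(f"unknown surrogate pool {pool!r}")


def surrogate_enrichment(
    sig_rois_by_rsn: dict[str, set],
    table: TermTable,
    atlas: Atlas,
    n_surrogates: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    pool: str = "atlas",
) -> pd.DataFrame:
    """Term-frequency z-scores against equal-size random surrogate ROI sets.

    Degenerate surrogate distributions (sd = 0) get a permutation-style
    floor: observed > mean maps to p = 1/(n_surrogates + 1), observed <=
    mean to p = 1, keeping the ordering finite.
    """
    if n_surrogates < 2:
        raise InputError(f"need n_surrogates >= 2, got {n_surrogates}")
    rng = np.random.default_rng(seed)
    all_terms = sorted({t for terms in table.values() for t in terms})
    rows = []
    for rsn in sorted(sig_rois_by_rsn):
        sig = sorted(sig_rois_by_rsn[rsn])
        if not sig:
            raise InputError(f"empty significant ROI set for RSN {rsn!r}")
        observed = term_counts(sig, table)
        pool_rois = np.array(_surrogate_pool(atlas, rsn, pool))
        if len(sig) > len(pool_rois):
            raise InputError(
                f"significant set for {rsn!r} larger than surrogate pool"
            )
        surro = np.zeros((n_surrogates, len(all_terms)))
        t_index = {t: k for k, t in enumerate(all_terms)}
        for s in range(n_surrogates):
            draw = rng.choice(pool_rois, size=len(sig), replace=False)
            for term, c in term_counts(draw, table).items():
                surro[s, t_index[term]] = c
        mean = surro.mean(axis=0)
        sd = surro.std(axis=0, ddof=1)
        p_floor = 1.0 / (n_surrogates + 1)
        for term in all_terms:
            k = t_index[term]
            obs = observed.get(term, 0)
            if sd[k] > 0:
                z = (obs - mean[k]) / sd[k]
                p = float(norm.sf(z))
            elif obs > mean[k]:
                p = p_floor
                z = float(norm.isf(p))
            else:
                p = 1.0
                z = 0.0 if obs == mean[k] else float(-norm.isf(p_floor))
            rows.append(
                {
                    "rsn": rsn,
                    "term": term,
                    "observed": obs,
                    "surrogate_mean": mean[k],
                    "surrogate_sd": sd[k],
                    "z": z,
                    "p": p,
                }
            )
    df = pd.DataFrame(rows)
    adj = np.empty(len(df))
    flag = np.empty(len(df), dtype=bool)
    for rsn in df["rsn"].unique():
        m = df["rsn"] == rsn
        adj[m.to_numpy()], flag[m.to_numpy()] = bh_fdr(df.loc[m, "p"].to_numpy(), alpha)
    df["p_adj"] = adj
    df["significant"] = flag
    return df


def write_term_table(table: TermTable, path) -> None:
    rows = [(roi, term) for roi in sorted(table) for term in table[roi]]
    pd.DataFrame(rows, columns=["roi_id", "term"]).to_csv(path, sep="\t", index=False)


def read_term_table(path) -> TermTable:
    df = pd.read_csv(path, sep="\t")
    if not {"roi_id", "term"} <= set(df.columns):
        raise InputError(f"{path}: term table needs columns roi_id, term")
    table: TermTable = {}
    for _, row in df.iterrows():
        table.setdefault(int(row["roi_id"]), []).append(str(row["term"]))
    return table
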