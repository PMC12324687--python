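"""Gene-category enrichment against an ensemble of spatial-null target maps.

A category score is the mean Fisher-z-transformed Pearson correlation of its
member annotation maps with a target map. Significance comes from an
ensemble null: the *target* is replaced by each null map (a spun or
surrogate version of itself), the category scores are recomputed, and a
positive-sided inclusive permutation p-value is taken per category,
followed by Benjamini-Hochberg FDR across categories.

Annotations with low differential stability (mean inter-donor correlation)
can be filtered out before scoring, and categories are restricted to those
with more than ``min_size`` members after filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import AnnotationSet
from .nulls import NullEnsemble, apply_ensemble, bh_fdr

__all__ = [
    "CategorySet",
    "differential_stability",
    "category_score",
    "run_gcea",
    "read_categories",
    "write_enrichment_table",
]

_Z_CLIP = 1.0 - 1e-7  # keep Fisher z finite at |r| = 1


@dataclass
class CategorySet:
    """Category membership lists with the filtering thresholds applied to them."""

    categories: Dict[str, List[str]]
    min_size: int = 30
    ds_threshold: Optional[float] = 0.1


def differential_stability(donor_maps: np.ndarray) -> np.ndarray:
    """Mean pairwise inter-donor correlation per annotation.

    ``donor_maps`` has shape (n_donors, n_annotations, n_parcels). Donor
    pairs where either map has zero variance are skipped; an annotation with
    no usable pair raises.
    """
    donor_maps = np.asarray(donor_maps, dtype=float)
    if donor_maps.ndim != 3 or donor_maps.shape[0] < 2:
        raise ValueError("need maps for at least 2 donors")
    n_donors, n_ann, _ = donor_maps.shape
    ds = np.empty(n_ann)
    for a in range(n_ann):
        rs = []
        for i in range(n_donors):
            for j in range(i + 1, n_donors):
                x, y = donor_maps[i, a], donor_maps[j, a]
                if x.std() == 0 or y.std() == 0:
                    continue
                rs.append(np.corrcoef(x, y)[0, 1])
        if not rs:
            raise ValueError(f"differential stability undefined for annotation {a}")
        ds[a] = np.mean(rs)
    return ds


def _corr_rows(maps: np.ndarray, target: np.ndarray) -> np.ndarray:
    mz = maps - maps.mean(axis=1, keepdims=True)
    tz = target - target.mean()
    denom = np.sqrt((mz ** 2).sum(axis=1) * (tz ** 2).sum())
    return (mz @ tz) / denom


def category_score(target: np.ndarray, member_maps: np.ndarray) -> float:
    """Mean Fisher-z correlation of member maps with the target.

    r is clipped to |r| <= 1 - 1e-7 before atanh so scores stay finite.
    """
    member_maps = np.atleast_2d(np.asarray(member_maps, dtype=float))
    if member_maps.shape[0] < 1:
        raise ValueError("need at least one member map")
    sds = member_maps.std(axis=1)
    bad = np.where(sds == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance member map(s) at rows {bad[:5].tolist()}")
    r = _corr_rows(member_maps, np.asarray(target, dtype=float))
    return float(np.mean(np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))))


def run_gcea(target: np.ndarray, annotations: AnnotationSet,
             ensemble: NullEnsemble, min_size: int = 30,
             ds_threshold: Optional[float] = 0.1, q: float = 0.05) -> pd.DataFrame:
    """Category enrichment table for a target map.

    The observed score per category is compared against scores recomputed
    with the target replaced by each null map from the ensemble (the
    annotation maps are never permuted). Returns a frame sorted by score,
    descending (stable), with columns: category, score, score_z (observed
    score standardized against its null mean/sd), null_mean, null_sd, p,
    p_fdr, n_members.
    """
    target = np.asarray(target, dtype=float)
    maps = annotations.maps
    keep_names = list(maps.index)
    if ds_threshold is not None and annotations.donor_maps is not None:
        ds = differential_stability(annotations.donor_maps)
        keep_names = [n for n, d in zip(maps.index, ds) if d >= ds_threshold]
    name_to_row = {n: i for i, n in enumerate(maps.index)}

    retained = {}
    for cid, members in annotations.categories.items():
        kept = [m for m in members if m in set(keep_names)]
        if len(kept) > min_size:
            retained[cid] = kept
    if not retained:
        raise ValueError("no categories retained after size/stability filtering")

    all_maps = maps.to_numpy(dtype=float)
    null_targets = apply_ensemble(ensemble, target)        # n_null x parcels

    # correlations of every annotation with target and with every null target
    r_obs = _corr_rows(all_maps, target)
    tz = null_targets - null_targets.mean(axis=1, keepdims=True)
    mz = all_maps - all_maps.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.outer((mz ** 2).sum(axis=1), (tz ** 2).sum(axis=1)))
    r_null = (mz @ tz.T) / denom                            # n_ann x n_null
    z_obs = np.arctanh(np.clip(r_obs, -_Z_CLIP, _Z_CLIP))
    z_null = np.arctanh(np.clip(r_null, -_Z_CLIP, _Z_CLIP))

    rows = []
    n_null = ensemble.n_null
    for cid, members in retained.items():
        idx = np.array([name_to_row[m] for m in members])
        score = float(z_obs[idx].mean())
        null_scores = z_null[idx].mean(axis=0)
        null_mean = float(null_scores.mean())
        null_sd = float(null_scores.std(ddof=1))
        p = float((1 + np.sum(null_scores >= score)) / (1 + n_null))
        score_z = (score - null_mean) / null_sd if null_sd > 0 else np.inf
        rows.append((cid, score, score_z, null_mean, null_sd, p, len(members)))
    table = pd.DataFrame(rows, columns=["category", "score", "score_z",
                                        "null_mean", "null_sd", "p", "n_members"])
    adjusted, _ = bh_fdr(table["p"].to_numpy(), q=q)
    table["p_fdr"] = adjusted
    table = table.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    return table[["category", "score", "score_z", "null_mean", "null_sd",
                  "p", "p_fdr", "n_members"]]


def read_categories(path) -> Dict[str, List[str]]:
    """Read categories from two-column TSV (category_id, member) or GMT lines."""
    from pathlib import Path
    text = Path(path).read_text().strip().splitlines()
    categories: Dict[str, List[str]] = {}
    first = text[0].split("\t") if text else []
    if len(first) == 2 and first != ["category_id", "member"]:
        pairs = [ln.split("\t") for ln in text]
    elif first == ["category_id", "member"]:
        pairs = [ln.split("\t") for ln in text[1:]]
    else:  # GMT: name <tab> description <tab> members...
        for ln in text:
            fields = ln.split("\t")
            categories[fields[0]] = fields[2:]
        return categories
    for cid, member in pairs:
        categories.setdefault(cid, []).append(member)
    return categories


def write_enrichment_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
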