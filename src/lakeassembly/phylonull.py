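"""Phylogenetic and abundance-based null models of community assembly.

Implements the Stegen et al. framework the field uses to partition
community assembly into five processes:

* βMNTD — abundance-weighted mean nearest-taxon phylogenetic distance
  between two communities;
* βNTI — z-score of the observed βMNTD against a null distribution
  obtained by shuffling taxon labels across the cophenetic matrix
  (equivalently, shuffling tips of the tree); |βNTI| > 2 signals
  deterministic selection;
* RC(Bray) — Raup–Crick index in [-1, 1] from a null that reassembles
  each community at observed richness and read total with probabilities
  proportional to metacommunity occupancy and abundance; |RC| > 0.95
  signals non-random turnover in the absence of a selection signal;
* a five-way classification of each sample pair (variable selection,
  homogeneous selection, dispersal limitation, homogenizing dispersal,
  undominated) with per-group process fractions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import AbundanceMatrix, relative_abundance
from .exceptions import FormatError, InvalidInputError

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


def cophenetic(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Patristic (tip-to-tip path length) distance matrix of a tree.

    Every non-root branch must carry a length; the matrix is symmetric
    with zero diagonal.
    """
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError(
                f"branch above {node.name or 'an internal node'!r} has no length"
            )
    dm = tree.tip_tip_distances()
    return list(dm.ids), np.asarray(dm.data, dtype=float)


def bmntd(x, y, distances: np.ndarray, weighted: bool = True) -> float:
    """β mean nearest taxon distance between two communities.

    ``x`` and ``y`` are abundance vectors aligned to the rows/columns of
    ``distances``. Each present taxon contributes the distance to its
    nearest relative in the other community, weighted by its relative
    abundance renormalized over the community's present taxa (uniform
    weights when ``weighted=False``); the two directed means are averaged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ix = np.flatnonzero(x > 0)
    iy = np.flatnonzero(y > 0)
    if ix.size == 0 or iy.size == 0:
        raise InvalidInputError("bmntd undefined for an empty community")
    sub = distances[np.ix_(ix, iy)]
    near_x = sub.min(axis=1)  # for each taxon in x, nearest in y
    near_y = sub.min(axis=0)
    if weighted:
        fx = x[ix] / x[ix].sum()
        fy = y[iy] / y[iy].sum()
    else:
        fx = np.full(ix.size, 1.0 / ix.size)
        fy = np.full(iy.size, 1.0 / iy.size)
    return float(0.5 * (fx @ near_x + fy @ near_y))


def _bmntd_all_pairs(weights: np.ndarray, mask: np.ndarray, distances: np.ndarray) -> np.ndarray:
    """βMNTD for every sample pair at once.

    ``weights`` holds per-sample relative abundances renormalized over
    present taxa (zeros elsewhere); ``mask`` the presence matrix. For
    each sample s, nd[s, t] = distance from taxon t to its nearest taxon
    present in s; the pair matrix then reduces to one matmul.
    """
    n_samples, n_taxa = mask.shape
    nd = np.empty((n_samples, n_taxa))
    for s in range(n_samples):
        nd[s] = distances[:, mask[s]].min(axis=1)
    g = weights @ nd.T  # g[a, b] = sum_t w_a[t] * nd[b, t]
    return 0.5 * (g + g.T)


def _community_weights(m: AbundanceMatrix, weighted: bool) -> tuple[np.ndarray, np.ndarray]:
    rel = relative_abundance(m)
    mask = m.counts > 0
    if not weighted:
        rel = mask.astype(float)
    w = np.where(mask, rel, 0.0)
    sums = w.sum(axis=1, keepdims=True)
    return w / sums, mask


def bnti_pairwise(
    m: AbundanceMatrix,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """Observed βMNTD and βNTI for every sample pair.

    The null randomizes taxon identities across the cophenetic matrix;
    one shared label permutation per null round is applied to all pairs.
    βNTI = (βMNTD_obs - mean_null) / sd_null. Pairs whose null spread is
    zero (e.g. compositionally identical samples) get NaN βNTI and are
    flagged in the ``defined`` column rather than raising.
    """
    if m.n_samples < 2:
        raise InvalidInputError("need at least 2 samples")
    taxa, dist = cophenetic(tree)
    missing = set(m.taxon_ids) - set(taxa)
    if missing:
        raise InvalidInputError(
            f"{len(missing)} matrix taxa absent from the tree, e.g. {sorted(missing)[0]!r}"
        )
    order = [taxa.index(t) for t in m.taxon_ids]
    dist = dist[np.ix_(order, order)]

    weights, mask = _community_weights(m, weighted)
    obs = _bmntd_all_pairs(weights, mask, dist)

    rng = np.random.default_rng(seed)
    total = np.zeros_like(obs)
    total_sq = np.zeros_like(obs)
    n_taxa = m.n_taxa
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        null = _bmntd_all_pairs(weights, mask, dist[np.ix_(perm, perm)])
        total += null
        total_sq += null**2
    mean_null = total / n_null
    var_null = (total_sq - n_null * mean_null**2) / max(n_null - 1, 1)
    sd_null = np.sqrt(np.clip(var_null, 0.0, None))

    rows = []
    n_undefined = 0
    for i in range(m.n_samples):
        for j in range(i + 1, m.n_samples):
            sd = sd_null[i, j]
            defined = sd > 1e-12
            if not defined:
                n_undefined += 1
            rows.append(
                {
                    "sample_i": m.sample_ids[i],
                    "sample_j": m.sample_ids[j],
                    "bmntd_obs": obs[i, j],
                    "bnti": (obs[i, j] - mean_null[i, j]) / sd if defined else np.nan,
                    "defined": bool(defined),
                }
            )
    if n_undefined:
        warnings.warn(f"{n_undefined} pair(s) have zero null spread; βNTI undefined")
    return pd.DataFrame(rows)


def null_community(
    rng: np.random.Generator,
    occupancy_weights: np.ndarray,
    abundance_weights: np.ndarray,
    n_present: int,
    total: int,
) -> np.ndarray:
    """Draw one Raup–Crick null community.

    ``n_present`` taxa are sampled without replacement with probability
    proportional to metacommunity occupancy (Gumbel top-k), each is
    seeded with one individual, and the remaining ``total - n_present``
    individuals are allocated multinomially proportional to metacommunity
    relative abundance among the drawn taxa.
    """
    keys = np.log(occupancy_weights) + rng.gumbel(size=occupancy_weights.size)
    chosen = np.argpartition(-keys, n_present - 1)[:n_present]
    counts = np.zeros(occupancy_weights.size, dtype=np.int64)
    counts[chosen] = 1
    if total > n_present:
        p = abundance_weights[chosen]
        counts[chosen] += rng.multinomial(total - n_present, p / p.sum())
    return counts


def _bc_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.abs(a - b).sum(axis=1) / (a + b).sum(axis=1)


def rc_bray(
    m: AbundanceMatrix,
    n_null: int = 999,
    seed: int = 0,
    occupancy_weights: np.ndarray | None = None,
    abundance_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Abundance-based Raup–Crick index for every sample pair.

    For each pair, ``n_null`` pairs of null communities are assembled at
    the observed richness and read totals (see :func:`null_community`);
    the Bray–Curtis dissimilarity of each null pair is compared with the
    observed one and rc = 2 * ((#below + 0.5 * #ties) / n_null - 0.5),
    bounded in [-1, 1]. Ties count half.

    The metacommunity weights default to the occupancy and mean relative
    abundance of ``m`` itself; pass ``occupancy_weights`` and
    ``abundance_weights`` (aligned to the taxon axis) to judge pairs
    against an external metacommunity instead.
    """
    if m.n_samples < 2:
        raise InvalidInputError("need at least 2 samples")
    totals = m.counts.sum(axis=1)
    if np.any(totals == 0):
        bad = m.sample_ids[int(np.argmax(totals == 0))]
        raise InvalidInputError(f"sample {bad!r} has zero total count")
    occ = (
        np.asarray(occupancy_weights, dtype=float)
        if occupancy_weights is not None
        else (m.counts > 0).sum(axis=0).astype(float)
    )
    meta_ab = (
        np.asarray(abundance_weights, dtype=float)
        if abundance_weights is not None
        else relative_abundance(m).mean(axis=0)
    )
    present = occ > 0
    richness = (m.counts > 0).sum(axis=1)

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(m.n_samples):
        for j in range(i + 1, m.n_samples):
            bc_obs = np.abs(m.counts[i] - m.counts[j]).sum() / (totals[i] + totals[j])
            null_i = np.vstack(
                [
                    null_community(rng, occ[present], meta_ab[present], richness[i], totals[i])
                    for _ in range(n_null)
                ]
            )
            null_j = np.vstack(
                [
                    null_community(rng, occ[present], meta_ab[present], richness[j], totals[j])
                    for _ in range(n_null)
                ]
            )
            bc_null = _bc_pairs(null_i, null_j)
            below = np.count_nonzero(bc_null < bc_obs - 1e-12)
            ties = np.count_nonzero(np.abs(bc_null - bc_obs) <= 1e-12)
            rc = 2.0 * ((below + 0.5 * ties) / n_null - 0.5)
            rows.append(
                {
                    "sample_i": m.sample_ids[i],
                    "sample_j": m.sample_ids[j],
                    "bc_obs": bc_obs,
                    "rc": rc,
                }
            )
    return pd.DataFrame(rows)


def classify_process(bnti: float, rc: float | None = None) -> str:
    """Five-way assembly-process label from βNTI and RC thresholds.

    βNTI > 2 → variable selection; βNTI < -2 → homogeneous selection;
    otherwise RC > 0.95 → dispersal limitation, RC < -0.95 → homogenizing
    dispersal, |RC| ≤ 0.95 → undominated.
    """
    if not np.isfinite(bnti):
        raise InvalidInputError("bnti must be finite")
    if bnti > 2:
        return "variable_selection"
    if bnti < -2:
        return "homogeneous_selection"
    if rc is None or not np.isfinite(rc):
        raise InvalidInputError("rc required when |bnti| <= 2")
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def classify_pairs(bnti_df: pd.DataFrame, rc_df: pd.DataFrame) -> pd.DataFrame:
    """Join βNTI and RC tables on sample pairs and attach process labels.

    Pairs with undefined βNTI keep a null label and are excluded from
    summaries (counted separately).
    """
    merged = bnti_df.merge(rc_df, on=["sample_i", "sample_j"], how="inner")
    labels = []
    for _, row in merged.iterrows():
        if not np.isfinite(row["bnti"]):
            labels.append(None)
        else:
            labels.append(classify_process(row["bnti"], row["rc"]))
    merged["process"] = labels
    return merged


def summarize_processes(pairs: pd.DataFrame, grouping: str | None = None) -> pd.DataFrame:
    """Per-group fraction of pairs assigned to each of the five processes.

    ``grouping`` names a column of ``pairs``; None summarizes all pairs
    as one group. Unclassified (undefined-statistic) pairs are excluded
    from the fractions and reported in ``n_undefined``.
    """
    df = pairs.copy()
    if grouping is None:
        df["_group"] = "all"
        grouping = "_group"
    out = []
    for group, sub in df.groupby(grouping):
        classified = sub[sub["process"].notna()]
        if classified.empty:
            warnings.warn(f"group {group!r} has no classified pairs; skipped")
            continue
        frac = classified["process"].value_counts(normalize=True)
        row = {"group": group, "n_pairs": len(classified), "n_undefined": int(sub["process"].isna().sum())}
        for proc in PROCESSES:
            row[proc] = float(frac.get(proc, 0.0))
        out.append(row)
    return pd.DataFrame(out)


def assembly_analysis(
    m: AbundanceMatrix,
    tree: TreeNode,
    metadata: pd.DataFrame | None = None,
    group_keys=("lake", "fraction"),
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full βNTI + RC + classification, within metadata-defined groups.

    Null models run per group (pairs are only formed within a group);
    returns the long pair table and the per-group process summary.
    """
    if metadata is None:
        pairs = classify_pairs(
            bnti_pairwise(m, tree, n_null=n_null, seed=seed, weighted=weighted),
            rc_bray(m, n_null=n_null, seed=seed + 1),
        )
        pairs.insert(0, "group", "all")
        return pairs, summarize_processes(pairs, "group")

    md = metadata.copy()
    if "sample_id" in md.columns:
        md = md.set_index("sample_id")
    labels = md.loc[m.sample_ids, list(group_keys)].astype(str).agg("|".join, axis=1)
    all_pairs = []
    df = m.to_dataframe()
    for k, group in enumerate(sorted(labels.unique())):
        ids = [s for s in m.sample_ids if labels[s] == group]
        if len(ids) < 2:
            warnings.warn(f"group {group!r} has fewer than 2 samples; skipped")
            continue
        sub_df = df.loc[ids]
        sub_df = sub_df.loc[:, sub_df.sum(axis=0) > 0]
        sub = AbundanceMatrix.from_dataframe(sub_df)
        sub_tree = tree.shear(list(sub.taxon_ids))
        pairs = classify_pairs(
            bnti_pairwise(sub, sub_tree, n_null=n_null, seed=seed + 2 * k, weighted=weighted),
            rc_bray(sub, n_null=n_null, seed=seed + 2 * k + 1),
        )
        pairs.insert(0, "group", group)
        all_pairs.append(pairs)
    if not all_pairs:
        raise InvalidInputError("no group had at least 2 samples")
    pairs = pd.concat(all_pairs, ignore_index=True)
    return pairs, summarize_processes(pairs, "group")
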