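"""Partial least squares path modelling (PLS-PM).

Latent variables (LVs) are estimated from blocks of manifest variables
by the classic Lohmöller iteration: outer approximation (standardized
weighted sum of each block), inner approximation (weighted sum of
adjacent LV scores under the centroid / factor / path scheme), and a
mode-A weight update (covariance of each manifest with its block's inner
proxy), repeated until the outer weights stabilize. Path coefficients
are then ordinary least squares of each endogenous LV score on its
predecessors' scores; goodness of fit is
GoF = sqrt(mean communality x mean R^2). Path significance comes from a
sign-aligned nonparametric bootstrap with a two-sided percentile test;
the conventional ecology threshold alpha = 0.1 is the default flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigError, FitError, InvalidInputError

SCHEMES = ("centroid", "factor", "path")


@dataclass
class PathModelSpec:
    """Blocks, inner structure and algorithm settings for one PLS-PM fit.

    ``blocks`` maps each LV name to its manifest-variable columns (every
    column in exactly one block, all blocks reflective / mode A);
    ``paths`` lists directed (source, target) edges of the acyclic inner
    model.
    """

    blocks: dict[str, list[str]]
    paths: list[tuple[str, str]]
    scheme: str = "centroid"
    max_iter: int = 300
    tol: float = 1e-6

    def __post_init__(self) -> None:
        errors = []
        if self.scheme not in SCHEMES:
            errors.append(f"unknown scheme {self.scheme!r}")
        seen = {}
        for lv, cols in self.blocks.items():
            if not cols:
                errors.append(f"block {lv!r} is empty")
            for c in cols:
                if c in seen:
                    errors.append(f"manifest {c!r} appears in blocks {seen[c]!r} and {lv!r}")
                seen[c] = lv
        g = nx.DiGraph(self.paths)
        unknown = [n for n in g.nodes if n not in self.blocks]
        if unknown:
            errors.append(f"path endpoints not in blocks: {unknown}")
        if not unknown and not nx.is_directed_acyclic_graph(g):
            errors.append("inner model contains a cycle")
        if errors:
            raise ConfigError("; ".join(errors))

    @property
    def lv_names(self) -> list[str]:
        return list(self.blocks)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.blocks)
        g.add_edges_from(self.paths)
        return g


@dataclass
class PathModelResult:
    spec: PathModelSpec
    outer_weights: pd.Series  # index (lv, manifest)
    loadings: pd.Series
    scores: pd.DataFrame = field(repr=False)  # samples x LVs, unit variance
    path_coefficients: pd.DataFrame  # columns source, target, coefficient
    r_squared: dict[str, float]
    communalities: pd.Series
    gof: float
    n_iter: int

    def path(self, source: str, target: str) -> float:
        df = self.path_coefficients
        row = df[(df["source"] == source) & (df["target"] == target)]
        if row.empty:
            raise KeyError(f"no inner edge {source!r} -> {target!r}")
        return float(row["coefficient"].iloc[0])


def _standardize(x: np.ndarray, names, what: str) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = names[int(np.argmax(sd == 0))]
        raise InvalidInputError(f"constant {what} column {bad!r}")
    return (x - x.mean(axis=0)) / sd


def fit_plspm(
    data: pd.DataFrame,
    spec: PathModelSpec,
    dropna: bool = False,
    _align_to: pd.Series | None = None,
) -> PathModelResult:
    """Fit a PLS path model to a samples x variables table.

    Manifest columns are standardized; missing values raise unless
    ``dropna`` requests listwise deletion. Each LV score is fixed to
    correlate positively with the bulk of its own block (sign convention)
    unless ``_align_to`` supplies reference outer weights (used by the
    bootstrap to keep replicate orientations comparable).
    """
    manifests = [c for cols in spec.blocks.values() for c in cols]
    missing_cols = [c for c in manifests if c not in data.columns]
    if missing_cols:
        raise InvalidInputError(f"data lacks manifest columns {missing_cols}")
    sub = data[manifests]
    if sub.isna().any().any():
        if dropna:
            sub = sub.dropna()
        else:
            bad = sub.columns[sub.isna().any()][0]
            raise InvalidInputError(
                f"missing values in manifest column {bad!r}; pass dropna=True for listwise deletion"
            )
    n = len(sub)
    if n < 3:
        raise InvalidInputError("need at least 3 complete rows")
    if n <= len(manifests):
        warnings.warn("fewer samples than manifest variables; estimates will be unstable")

    lvs = spec.lv_names
    block_x = {
        lv: _standardize(sub[cols].to_numpy(dtype=float), cols, "manifest")
        for lv, cols in spec.blocks.items()
    }
    g = spec.graph()
    neighbors = {
        lv: sorted(set(g.predecessors(lv)) | set(g.successors(lv))) for lv in lvs
    }
    if any(not nb for nb in neighbors.values()):
        isolated = [lv for lv, nb in neighbors.items() if not nb]
        raise ConfigError(f"latent variable(s) {isolated} are not connected to the inner model")

    w = {lv: np.ones(len(spec.blocks[lv])) for lv in lvs}

    def outer_scores(w):
        y = {}
        for lv in lvs:
            score = block_x[lv] @ w[lv]
            sd = score.std(ddof=1)
            if sd == 0:
                raise FitError(f"degenerate score for {lv!r}")
            y[lv] = score / sd
        return y

    y = outer_scores(w)
    converged = False
    for it in range(1, spec.max_iter + 1):
        # inner weights
        e = {lv: {} for lv in lvs}
        for lv in lvs:
            if spec.scheme == "path":
                preds = sorted(g.predecessors(lv))
                if preds:
                    z_mat = np.column_stack([y[p] for p in preds])
                    coef, *_ = np.linalg.lstsq(z_mat, y[lv], rcond=None)
                    for p, c in zip(preds, coef):
                        e[lv][p] = c
                for s in g.successors(lv):
                    e[lv][s] = np.corrcoef(y[lv], y[s])[0, 1]
            else:
                for nb in neighbors[lv]:
                    r = np.corrcoef(y[lv], y[nb])[0, 1]
                    e[lv][nb] = np.sign(r) if spec.scheme == "centroid" else r
        # inner proxies and mode-A weight update
        w_new = {}
        for lv in lvs:
            z = np.zeros(n)
            for nb, c in e[lv].items():
                z += c * y[nb]
            zsd = z.std(ddof=1)
            if zsd == 0:
                raise FitError(f"degenerate inner proxy for {lv!r}")
            z /= zsd
            w_new[lv] = block_x[lv].T @ z / (n - 1)  # cov(manifest, proxy)
        y_new = outer_scores(w_new)
        # sign convention per block
        for lv in lvs:
            ref = w[lv] if _align_to is None else _align_to[lv].to_numpy()
            orient = block_x[lv].T @ y_new[lv] if _align_to is None else w_new[lv]
            flip = (orient.sum() < 0) if _align_to is None else (np.dot(w_new[lv], ref) < 0)
            if flip:
                w_new[lv] = -w_new[lv]
                y_new[lv] = -y_new[lv]
        delta = max(
            np.max(np.abs(np.abs(w_new[lv]) / np.linalg.norm(w_new[lv]) - np.abs(w[lv]) / np.linalg.norm(w[lv])))
            for lv in lvs
        )
        w, y = w_new, y_new
        if delta < spec.tol and it > 1:
            converged = True
            break
    if not converged:
        raise FitError(
            f"outer weights did not converge in {spec.max_iter} iterations (last delta {delta:.3g})"
        )

    # final orientation: majority of loadings positive (unless aligned)
    if _align_to is None:
        for lv in lvs:
            load = np.array([np.corrcoef(block_x[lv][:, k], y[lv])[0, 1] for k in range(block_x[lv].shape[1])])
            if load.sum() < 0:
                w[lv] = -w[lv]
                y[lv] = -y[lv]

    scores = pd.DataFrame({lv: y[lv] for lv in lvs}, index=sub.index)
    outer = {}
    loadings = {}
    for lv in lvs:
        wn = w[lv] / np.linalg.norm(w[lv])
        for k, col in enumerate(spec.blocks[lv]):
            outer[(lv, col)] = wn[k]
            loadings[(lv, col)] = float(np.corrcoef(block_x[lv][:, k], y[lv])[0, 1])
    outer = pd.Series(outer, name="weight")
    loadings = pd.Series(loadings, name="loading")
    communalities = (loadings**2).rename("communality")

    rows = []
    r2 = {}
    for lv in lvs:
        preds = sorted(g.predecessors(lv))
        if not preds:
            continue
        z_mat = np.column_stack([y[p] for p in preds])
        coef, *_ = np.linalg.lstsq(z_mat, y[lv], rcond=None)
        fitted = z_mat @ coef
        r2[lv] = float(1.0 - np.sum((y[lv] - fitted) ** 2) / np.sum((y[lv] - y[lv].mean()) ** 2))
        for p, c in zip(preds, coef):
            rows.append({"source": p, "target": lv, "coefficient": float(c)})
    paths_df = pd.DataFrame(rows, columns=["source", "target", "coefficient"])
    gof = float(np.sqrt(communalities.mean() * np.mean(list(r2.values())))) if r2 else float("nan")

    return PathModelResult(
        spec=spec,
        outer_weights=outer,
        loadings=loadings,
        scores=scores,
        path_coefficients=paths_df,
        r_squared=r2,
        communalities=communalities,
        gof=gof,
        n_iter=it,
    )


def bootstrap_paths(
    data: pd.DataFrame,
    spec: PathModelSpec,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.1,
    dropna: bool = False,
) -> pd.DataFrame:
    """Bootstrap standard errors and p-values for every inner path.

    Samples are resampled with replacement; each replicate is re-fitted
    with its LV orientations aligned to the full-data solution. The
    p-value is the two-sided percentile test of zero: twice the smaller
    tail fraction of replicate coefficients, capped at 1.
    """
    full = fit_plspm(data, spec, dropna=dropna)
    ref = {lv: full.outer_weights[lv] for lv in spec.lv_names}
    rng = np.random.default_rng(seed)
    rows = data.index.to_numpy()
    boots = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(rows), len(rows))
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            res = fit_plspm(sample, spec, dropna=dropna, _align_to=ref)
        except (FitError, InvalidInputError):
            failures += 1
            continue
        boots.append(res.path_coefficients.set_index(["source", "target"])["coefficient"])
    if failures > 0.1 * n_boot:
        warnings.warn(f"{failures}/{n_boot} bootstrap replicates failed to converge")
    if not boots:
        raise FitError("all bootstrap replicates failed")
    boot_df = pd.DataFrame(boots)

    out = []
    for _, row in full.path_coefficients.iterrows():
        key = (row["source"], row["target"])
        vals = boot_df[key].dropna().to_numpy()
        p = min(1.0, 2.0 * min(np.mean(vals <= 0), np.mean(vals >= 0)))
        out.append(
            {
                "source": key[0],
                "target": key[1],
                "coefficient": row["coefficient"],
                "se": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "p_value": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(out)


def indirect_effects(result: PathModelResult) -> pd.DataFrame:
    """Direct, indirect and total effects between every ordered LV pair.

    The indirect effect is the sum over all directed paths of length >= 2
    of the product of path coefficients along the path.
    """
    g = nx.DiGraph()
    for _, row in result.path_coefficients.iterrows():
        g.add_edge(row["source"], row["target"], weight=row["coefficient"])
    g.add_nodes_from(result.spec.lv_names)
    rows = []
    for src in result.spec.lv_names:
        for dst in result.spec.lv_names:
            if src == dst:
                continue
            direct = g[src][dst]["weight"] if g.has_edge(src, dst) else 0.0
            indirect = 0.0
            for path in nx.all_simple_paths(g, src, dst):
                if len(path) < 3:
                    continue
                prod = 1.0
                for a, b in zip(path[:-1], path[1:]):
                    prod *= g[a][b]["weight"]
                indirect += prod
            if direct != 0.0 or indirect != 0.0:
                rows.append(
                    {
                        "source": src,
                        "target": dst,
                        "direct": direct,
                        "indirect": indirect,
                        "total": direct + indirect,
                    }
                )
    return pd.DataFrame(rows, columns=["source", "target", "direct", "indirect", "total"])


def default_block_spec(stability_column: str = "stability") -> PathModelSpec:
    """Shipped template linking environmental drivers to stability.

    The block layout (salinity, nutrients, physicochemical, particles,
    richness -> stability, with drivers also acting through richness) is
    an editable reconstruction of the conventional ecology layout, not a
    fixed contract; swap blocks and paths freely.
    """
    return PathModelSpec(
        blocks={
            "salinity": ["salinity", "conductivity"],
            "nutrients": ["NO3", "PO4", "NH3", "SO4", "DOC"],
            "physicochemical": ["temperature", "DO", "pH", "fDOM"],
            "particles": ["turbidity"],
            "richness": ["richness"],
            "stability": [stability_column],
        },
        paths=[
            ("salinity", "richness"),
            ("nutrients", "richness"),
            ("physicochemical", "richness"),
            ("particles", "richness"),
            ("salinity", "stability"),
            ("nutrients", "stability"),
            ("physicochemical", "stability"),
            ("particles", "stability"),
            ("richness", "stability"),
        ],
    )
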