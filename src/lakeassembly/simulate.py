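"""Synthetic community generators.

Every generator is a pure function of its configuration and seed: the same
inputs give byte-identical outputs. Four regimes are covered:

* :func:`simulate_tree` — pure-birth (Yule) ultrametric phylogenies;
* :func:`simulate_neutral` — communities drawn from the stationary
  distribution the Sloan neutral model assumes (Beta marginals driven by
  the metacommunity abundance and immigration rate, then multinomial
  read sampling);
* :func:`simulate_selection` — selection-structured communities whose
  niche optima evolve by Brownian motion on a phylogeny, so that niches
  are phylogenetically conserved along an environmental gradient;
* :func:`simulate_lake_timeseries` — monthly multi-depth, two-fraction
  lake campaigns with regime-dependent salinity and compositional
  turnover, plus a physicochemical metadata table.
"""

from __future__ import annotations

import io
import random
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from skbio import TreeNode

from .core import AbundanceMatrix
from .exceptions import InvalidInputError


# ---------------------------------------------------------------------------
# trees


def simulate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Simulate an ultrametric pure-birth (Yule) tree with ``n_taxa`` tips.

    Tips are relabelled ``taxon_0001`` .. deterministically; all branch
    lengths are positive. Returns a rooted ``skbio.TreeNode``.
    """
    if n_taxa < 2:
        raise InvalidInputError("a tree needs at least 2 tips")
    rng = random.Random(int(seed))
    dtree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=int(n_taxa),
        rng=rng,
    )
    # the process stops exactly at the n-th speciation, leaving two
    # zero-length tips; run time forward to the next (uncommitted) birth
    # event so every branch is positive and the tree stays ultrametric
    extra = rng.expovariate(float(n_taxa))
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"taxon_{i + 1:04d}"
        leaf.edge.length += extra
    newick = dtree.as_string(schema="newick", suppress_rooting=True).strip()
    return TreeNode.read(io.StringIO(newick))


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue()


def write_tree(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree))


def brownian_traits(tree: TreeNode, rate: float, seed: int) -> pd.Series:
    """Evolve a continuous trait by Brownian motion along the tree.

    The increment on each branch is N(0, rate * branch_length); tip values
    are returned keyed by tip name.
    """
    if rate <= 0:
        raise InvalidInputError("trait_evolution_rate must be positive")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    traits = {}
    for node in tree.preorder(include_self=False):
        length = node.length or 0.0
        values[id(node)] = values[id(node.parent)] + rng.normal(0.0, np.sqrt(rate * length))
        if node.is_tip():
            traits[node.name] = values[id(node)]
    return pd.Series(traits, name="trait")


# ---------------------------------------------------------------------------
# neutral metacommunity sampling


def metacommunity_abundances(
    n_taxa: int, kind: str = "lognormal", shape: float = 1.5, seed: int = 0
) -> np.ndarray:
    """Draw a long-tailed metacommunity species-abundance distribution.

    ``lognormal`` draws exp(N(0, shape)); ``logseries`` draws Fisher
    log-series counts with parameter ``shape`` in (0, 1). The result is
    normalized to sum to one.
    """
    rng = np.random.default_rng(seed)
    if kind == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=shape, size=n_taxa)
    elif kind == "logseries":
        if not 0 < shape < 1:
            raise InvalidInputError("logseries shape must be in (0,1)")
        raw = rng.logseries(shape, size=n_taxa).astype(float)
    else:
        raise InvalidInputError(f"unknown metacommunity kind {kind!r}")
    return raw / raw.sum()


@dataclass
class NeutralSimConfig:
    """Configuration for the neutral (Sloan) community generator.

    ``community_size`` is N, the number of individuals (reads) per local
    community; ``migration_rate`` is m, the probability that a death is
    replaced by an immigrant from the metacommunity rather than by local
    reproduction; ``abundances`` is the metacommunity relative-abundance
    vector p (auto-generated when None).
    """

    n_taxa: int
    n_samples: int
    community_size: int
    migration_rate: float
    abundances: np.ndarray | None = None
    metacommunity: str = "lognormal"
    sad_shape: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_samples < 1:
            raise InvalidInputError("n_taxa and n_samples must be positive")
        if self.community_size < 1:
            raise InvalidInputError("community_size N must be >= 1")
        if not 0 < self.migration_rate <= 1:
            raise InvalidInputError("migration_rate m must be in (0, 1]")
        if self.abundances is not None:
            p = np.asarray(self.abundances, dtype=float)
            if p.shape != (self.n_taxa,) or np.any(p <= 0):
                raise InvalidInputError("abundances must be positive, length n_taxa")
            if abs(p.sum() - 1.0) > 1e-12:
                raise InvalidInputError("abundances must sum to 1 within 1e-12")
            self.abundances = p

    def resolved_abundances(self) -> np.ndarray:
        if self.abundances is not None:
            return self.abundances
        return metacommunity_abundances(
            self.n_taxa, self.metacommunity, self.sad_shape, seed=self.seed + 7919
        )


def simulate_neutral(config: NeutralSimConfig) -> AbundanceMatrix:
    """Sample local communities from the Sloan stationary distribution.

    For each sample, each taxon's latent relative abundance is drawn from
    Beta(N*m*p_i, N*m*(1-p_i)) — the stationary marginal the neutral model
    fit assumes — renormalized across taxa, then N reads are drawn
    multinomially. Row sums equal N exactly.
    """
    rng = np.random.default_rng(config.seed)
    p = config.resolved_abundances()
    n, big_n, m = config.n_samples, config.community_size, config.migration_rate
    a = big_n * m * p
    b = big_n * m * (1.0 - p)
    latent = rng.beta(a, b, size=(n, config.n_taxa))
    sums = latent.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    latent /= sums
    counts = np.vstack([rng.multinomial(big_n, latent[i]) for i in range(n)])
    return AbundanceMatrix(
        counts,
        [f"sample_{i + 1:04d}" for i in range(n)],
        [f"taxon_{j + 1:04d}" for j in range(config.n_taxa)],
    )


# ---------------------------------------------------------------------------
# selection along an environmental gradient


@dataclass
class SelectionSimConfig:
    """Configuration for selection-structured communities.

    Niche optima (traits) evolve by Brownian motion on ``tree`` with
    variance ``trait_evolution_rate`` per unit branch length, so related
    taxa share similar optima. Taxon fitness in a sample is a Gaussian
    kernel of (trait - env) with width ``niche_breadth``; small breadths
    mean strong selection.
    """

    tree: TreeNode
    env_values: np.ndarray
    niche_breadth: float
    trait_evolution_rate: float = 1.0
    community_size: int = 10_000
    base_sad_shape: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.env_values = np.asarray(self.env_values, dtype=float)
        if self.niche_breadth <= 0:
            raise InvalidInputError("niche_breadth sigma must be positive")
        if self.trait_evolution_rate <= 0:
            raise InvalidInputError("trait_evolution_rate must be positive")
        if self.tree.count(tips=True) < 2:
            raise InvalidInputError("tree must have at least 2 tips")


def simulate_selection(config: SelectionSimConfig) -> AbundanceMatrix:
    """Draw communities filtered by a phylogenetically conserved niche.

    Expected composition in sample j is proportional to
    base_i * exp(-(trait_i - env_j)^2 / (2 sigma^2)); reads are multinomial.
    Samples with very different environments share few dominant taxa.
    """
    rng = np.random.default_rng(config.seed)
    taxa = [t.name for t in config.tree.tips()]
    traits = brownian_traits(
        config.tree, config.trait_evolution_rate, seed=config.seed + 104729
    ).reindex(taxa).to_numpy()
    base = rng.lognormal(0.0, config.base_sad_shape, size=len(taxa))
    counts = []
    for env in config.env_values:
        fitness = np.exp(-((traits - env) ** 2) / (2.0 * config.niche_breadth**2))
        w = base * fitness
        if w.sum() == 0:  # numerically dead community under extreme selection
            w = base
        counts.append(rng.multinomial(config.community_size, w / w.sum()))
    return AbundanceMatrix(
        np.vstack(counts),
        [f"sample_{i + 1:04d}" for i in range(len(config.env_values))],
        taxa,
    )


# ---------------------------------------------------------------------------
# lake campaign time series


@dataclass
class LakeSpec:
    name: str
    regime: str = "stable"  # "gradient" (seasonal seawater intrusion) or "stable"
    trophic: str = "oligotrophic"

    def __post_init__(self) -> None:
        if self.regime not in ("gradient", "stable"):
            raise InvalidInputError(f"unknown salinity regime {self.regime!r}")


@dataclass
class LakeScenario:
    """A monthly, multi-depth, two-fraction sampling campaign.

    ``months`` are 'YYYY-MM' strings, strictly increasing, at least two.
    ``turnover`` scales month-to-month compositional drift: 0 freezes the
    community exactly. For "gradient" lakes salinity follows a sinusoid
    peaking in late summer (seawater intrusion); selection against the
    salinity gradient enters the drift, so their turnover responds to the
    seasonal swing.
    """

    lakes: list[LakeSpec]
    months: list[str]
    depths: int = 2
    fractions: tuple[str, ...] = ("PA", "FL")
    n_taxa: int = 150
    community_size: int = 5_000
    turnover: float = 0.3
    salinity_amplitude: float = 8.0
    selection_sigma: float = 2.0

    def __post_init__(self) -> None:
        self.lakes = [
            lake if isinstance(lake, LakeSpec) else LakeSpec(**lake) for lake in self.lakes
        ]
        if len(self.months) < 2:
            raise InvalidInputError("a campaign needs at least 2 time points")
        stamps = [pd.Period(mo, freq="M") for mo in self.months]
        if any(b <= a for a, b in zip(stamps, stamps[1:])):
            raise InvalidInputError("months must be strictly increasing")
        if self.depths < 2:
            raise InvalidInputError("at least 2 depths per month")
        if self.turnover < 0:
            raise InvalidInputError("turnover must be >= 0")


def monthly_dates(start: str, n_months: int) -> list[str]:
    start_p = pd.Period(start, freq="M")
    return [str(start_p + k) for k in range(n_months)]


_DEPTH_GRID = (2, 10, 20, 30, 40, 50)


def _softmax(z: np.ndarray) -> np.ndarray:
    w = np.exp(z - z.max())
    return w / w.sum()


def _count_seed(root_seed: int, lake: str, fraction: str, depth: int, comp: np.ndarray):
    """Seed material for the read-sampling RNG: a pure function of the
    latent composition, so identical composition -> identical reads."""
    tag = f"{lake}|{fraction}|{depth}".encode()
    return [
        int(root_seed) % (2**31),
        zlib.crc32(tag),
        zlib.crc32(np.round(comp, 12).tobytes()),
    ]


def simulate_lake_timeseries(
    scenario: LakeScenario, seed: int = 0, return_tree: bool = False
):
    """Generate one row per (lake, month, depth, fraction) plus metadata.

    Community composition per (lake, fraction) performs a smooth latent
    random walk whose innovation scale is ``scenario.turnover``; in
    "gradient" lakes a salinity-selection term (also scaled by turnover)
    pushes composition with the seasonal salinity cycle. Metadata carries
    salinity, temperature, oxygen, pH, fDOM, turbidity, conductivity,
    nutrient and ion concentrations, and DOC with seasonal structure.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 2_147_483_629])
    n_taxa = scenario.n_taxa
    tree = simulate_tree(n_taxa, seed=(int(seed) + 31337) % (2**31))
    taxa = [t.name for t in tree.tips()]
    traits = brownian_traits(tree, 1.0, seed=(int(seed) + 271) % (2**31)).reindex(taxa)
    traits = ((traits - traits.mean()) / (traits.std() or 1.0)).to_numpy()
    log_meta = rng.normal(0.0, 1.5, n_taxa)
    depth_values = _DEPTH_GRID[: scenario.depths]

    months = scenario.months
    month_num = np.array([pd.Period(mo, freq="M").month for mo in months])
    season = np.cos(2 * np.pi * (month_num - 8) / 12.0)  # peaks in August

    rows, meta_rows = [], []
    sample_ids = []
    for lake in scenario.lakes:
        if lake.regime == "gradient":
            salinity = 2.0 + scenario.salinity_amplitude * 0.5 * (1.0 + season)
        else:
            salinity = np.full(len(months), 0.3)
        salinity = salinity + rng.normal(0.0, 0.05, len(months))
        env = (salinity - salinity.mean()) / (salinity.std() or 1.0)
        temperature = 12.0 + 9.0 * season + rng.normal(0.0, 0.5, len(months))
        trophic_load = {"oligotrophic": 0.3, "mesotrophic": 1.0, "eutrophic": 2.5}.get(
            lake.trophic, 1.0
        )
        for fraction in scenario.fractions:
            state = log_meta + rng.normal(0.0, 0.5, n_taxa)
            depth_offsets = {d: rng.normal(0.0, 0.2, n_taxa) for d in depth_values}
            prev_logfit = None
            for t, month in enumerate(months):
                logfit = -((traits - env[t]) ** 2) / (2.0 * scenario.selection_sigma**2)
                if lake.regime != "gradient":
                    logfit = np.zeros(n_taxa)
                if prev_logfit is not None:
                    drift = rng.normal(0.0, 1.0, n_taxa)
                    state = state + scenario.turnover * (drift + (logfit - prev_logfit))
                prev_logfit = logfit
                for d_i, depth in enumerate(depth_values):
                    comp = _softmax(state + depth_offsets[depth])
                    local_rng = np.random.default_rng(
                        _count_seed(seed, lake.name, fraction, depth, comp)
                    )
                    counts = local_rng.multinomial(scenario.community_size, comp)
                    sid = f"{lake.name}_{fraction}_{month}_d{depth:02d}m"
                    rows.append(counts)
                    sample_ids.append(sid)
                    sal_d = salinity[t] + (0.2 * d_i if lake.regime == "gradient" else 0.0)
                    temp_d = temperature[t] - 0.15 * depth
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "lake": lake.name,
                            "fraction": fraction,
                            "depth": float(depth),
                            "date": f"{month}-15",
                            "month": month,
                            "salinity": round(sal_d, 4),
                            "temperature": round(temp_d, 4),
                            "DO": round(11.0 - 0.25 * temp_d + rng.normal(0, 0.3), 4),
                            "pH": round(8.1 + rng.normal(0, 0.1), 4),
                            "fDOM": round(trophic_load * (8.0 + rng.normal(0, 1.0)), 4),
                            "turbidity": round(
                                trophic_load * (1.5 + 0.5 * season[t]) + abs(rng.normal(0, 0.3)),
                                4,
                            ),
                            "conductivity": round(250.0 + 1400.0 * sal_d / 35.0 + rng.normal(0, 10), 4),
                            "NO3": round(trophic_load * abs(0.5 + rng.normal(0, 0.15)), 4),
                            "PO4": round(trophic_load * abs(0.05 + rng.normal(0, 0.02)), 4),
                            "NH3": round(trophic_load * abs(0.1 + rng.normal(0, 0.04)), 4),
                            "SO4": round(3.0 + 70.0 * sal_d / 35.0 + rng.normal(0, 0.5), 4),
                            "Cl": round(5.0 + 550.0 * sal_d / 35.0 + rng.normal(0, 2.0), 4),
                            "DOC": round(trophic_load * (1.2 + rng.normal(0, 0.2)), 4),
                        }
                    )
    matrix = AbundanceMatrix(np.vstack(rows), sample_ids, taxa)
    metadata = pd.DataFrame(meta_rows)
    if return_tree:
        return matrix, metadata, tree
    return matrix, metadata
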