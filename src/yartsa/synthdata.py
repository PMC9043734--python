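"""Synthetic host/parasite systems with the statistical structure the
downstream analyses assume.

The generator produces, from one seeded configuration: an ultrametric
birth-death host tree; tip geography from a valley stepping-stone dispersal
process (within-valley diffusion plus distance-weighted colonization jumps)
with region labels by nearest-centroid (Voronoi) assignment; a parasite tree
that tracks the host tree but can switch hosts at cladogenesis; multi-locus
sequences whose realized mean pairwise divergence is calibrated to a target
(default 5% for hosts, with parasite branch lengths scaled to a fifth of the
host's, giving roughly the observed 1% fungal divergence); and per-sample
locus dropout (default rate chosen so an average sample keeps ~13.2 of 14
loci).

Every operation is a pure function of (inputs, seed): identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import distances
from ._utils import derive_seed
from .containers import (
    AssociationMatrix,
    MultiLocusAlignment,
    SampleTable,
    write_multilocus_fasta,
)
from .errors import ConfigError, SimulationError
from .models import BASES, SubstitutionModel
from .trees import Tree, TreeNode, write_newick

import pandas as pd

__all__ = [
    "SimConfig",
    "Bundle",
    "simulate_host_tree",
    "simulate_geography",
    "simulate_parasite_system",
    "simulate_sequences",
    "apply_locus_dropout",
    "simulate_bundle",
    "write_bundle",
    "annotate_region_clades",
    "mean_pairwise_distance",
]

# Rough centroids of the four sampling regions along the mountain arc
# (the commercial collection range runs from the western Nepal Himalaya to
# the eastern Hengduan mountains, ~2000 km).
DEFAULT_CENTROIDS = {
    "QTP": (35.5, 91.5),
    "Hengduan": (29.0, 101.0),
    "Himalaya": (28.0, 84.0),
    "Transition": (31.5, 96.0),
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator, with the study-scale defaults."""

    n_samples: int = 90
    centroids: dict = field(default_factory=lambda: dict(DEFAULT_CENTROIDS))
    birth_rate: float = 1.0
    death_rate: float = 0.2
    bm_rate: float = 0.2  # within-valley dispersal sigma^2, degrees^2 / time
    ou_strength: float = 0.35  # reversion toward the nearest valley (0 = BM)
    jump_rate: float = 0.4  # valley colonization events per unit time
    jump_scale_km: float = 400.0  # colonization distance kernel scale
    valleys_per_region: int = 4
    valley_scatter: float = 1.6  # valley spread around region centroids (deg)
    landing_scatter: float = 0.3  # post-colonization scatter (deg)
    root_location: tuple[float, float] | None = None
    n_loci: int = 14
    locus_length: int = 600
    model: str = "JC69"
    kappa: float = 2.0
    locus_rate_multipliers: tuple | None = None
    target_divergence: float = 0.05
    parasite_scale: float = 0.20
    p_switch: float = 0.1
    dropout: float = 0.057
    climate_intercept: float = 20.0
    climate_slope: float = -0.8  # degC per degree latitude
    climate_noise: float = 0.5
    year_range: tuple[int, int] = (1993, 2020)
    seed: int = 0

    def __post_init__(self):
        if not self.birth_rate > self.death_rate >= 0:
            raise ConfigError("require birth_rate > death_rate >= 0")
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if not self.centroids:
            raise ConfigError("at least one region centroid is required")
        if self.n_loci < 1 or self.locus_length < 1:
            raise ConfigError("n_loci and locus_length must be positive")
        for p in (self.p_switch, self.dropout):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.bm_rate < 0 or self.target_divergence <= 0:
            raise ConfigError("bm_rate must be >= 0 and target_divergence > 0")
        if self.ou_strength < 0 or self.jump_rate < 0:
            raise ConfigError("ou_strength and jump_rate must be >= 0")
        if self.valleys_per_region < 1 or self.jump_scale_km <= 0:
            raise ConfigError("need >= 1 valley per region and jump_scale_km > 0")
        mults = self.locus_rate_multipliers
        if mults is not None and len(mults) != self.n_loci:
            raise ConfigError("locus_rate_multipliers length must equal n_loci")

    @property
    def locus_names(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_loci)]

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(self.centroids)

    def substitution_model(self) -> SubstitutionModel:
        if self.model.upper() == "JC69":
            return SubstitutionModel.jc69()
        return SubstitutionModel.hky85(kappa=self.kappa)


# ----------------------------------------------------------------- host tree
def simulate_host_tree(config: SimConfig, seed: int | None = None) -> Tree:
    """Birth-death tree conditioned on ``n_samples`` surviving tips.

    Simulated forward from a crown pair of lineages; when the extant count
    first reaches n, all pendant branches are extended by the waiting time
    to the next (never realized) event, so a Yule tree's expected crown
    height is sum_{k=2..n} 1/(lambda k).
    """
    rng = np.random.default_rng(
        derive_seed(config.seed, "host_tree") if seed is None else seed
    )
    lam, mu, n = config.birth_rate, config.death_rate, config.n_samples
    for _ in range(1000):
        tree = _try_birth_death(rng, lam, mu, n)
        if tree is not None:
            return tree
    raise SimulationError("birth-death simulation went extinct 1000 times in a row")


def _try_birth_death(rng, lam: float, mu: float, n: int) -> Tree | None:
    root = TreeNode(None)
    active: list[tuple[TreeNode, float]] = []
    for _ in range(2):
        child = TreeNode(None)
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n:
        if not active:
            return None
        total = len(active) * (lam + mu)
        t += rng.exponential(1.0 / total)
        k = int(rng.integers(len(active)))
        node, start = active.pop(k)
        node.length = t - start
        if rng.random() < lam / (lam + mu):
            for _ in range(2):
                child = TreeNode(None)
                node.add_child(child)
                active.append((child, t))
        # else: death; node stays an unlabelled leaf and is pruned below
    t += rng.exponential(1.0 / (len(active) * (lam + mu)))
    for i, (node, start) in enumerate(active):
        node.length = t - start
        node.label = f"s{i + 1:03d}"
    _prune_unlabelled(root)
    if len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = 0.0
    tree = Tree(root)
    if tree.n_tips != n:
        return None
    # relabel in canonical tip order so labels are layout-independent
    tree.canonical_sort()
    for i, tip in enumerate(tree.tips()):
        tip.label = f"s{i + 1:03d}"
    return tree


def _prune_unlabelled(root: TreeNode) -> None:
    """Drop extinct (unlabelled) leaves and suppress unary nodes."""
    changed = True
    while changed:
        changed = False
        for node in list(_postorder(root)):
            if node.is_leaf and node.label is None and node.parent is not None:
                node.parent.children.remove(node)
                changed = True
            elif (
                not node.is_leaf
                and len(node.children) == 1
                and node.parent is not None
            ):
                child = node.children[0]
                child.length += node.length
                child.parent = node.parent
                node.parent.children[node.parent.children.index(node)] = child
                changed = True


def _postorder(root: TreeNode):
    stack = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            yield node
        else:
            stack.append((node, True))
            for c in reversed(node.children):
                stack.append((c, False))


# ---------------------------------------------------------------- geography
def simulate_geography(
    tree: Tree, config: SimConfig, seed: int | None = None
) -> SampleTable:
    """Tip coordinates by stepping-stone dispersal along the tree; region
    labels by nearest region centroid (great-circle); climate linear in
    latitude plus noise.

    The landscape is a set of discrete habitat patches ("valleys") scattered
    around the region centroids. A lineage diffuses within its current
    valley (rate ``bm_rate``, reversion ``ou_strength``) and colonizes other
    valleys at rate ``jump_rate``, preferring nearby ones (exponential
    kernel, scale ``jump_scale_km``). Genetic divergence therefore tracks
    geographic distance over a few valley hops and saturates beyond — the
    regime behind isolation-by-distance that is strongest at local scales.
    ``ou_strength=0`` with ``jump_rate=0`` recovers plain Brownian motion.
    """
    if not config.centroids:
        raise ConfigError("no region centroids configured")
    rng = np.random.default_rng(
        derive_seed(config.seed, "geography") if seed is None else seed
    )
    centroids = config.centroids
    names = list(centroids)
    clat = np.array([centroids[r][0] for r in names])
    clon = np.array([centroids[r][1] for r in names])

    # habitat patches: valleys_per_region points scattered around each centroid
    vlat, vlon = [], []
    for lat0, lon0 in zip(clat, clon):
        for _ in range(config.valleys_per_region):
            vlat.append(lat0 + rng.normal(0.0, config.valley_scatter))
            vlon.append(lon0 + rng.normal(0.0, config.valley_scatter))
    vlat = np.clip(np.array(vlat), -89.0, 89.0)
    vlon = np.array(vlon)

    if config.root_location is not None:
        root_lat, root_lon = config.root_location
    else:
        k0 = int(rng.integers(len(vlat)))
        root_lat, root_lon = float(vlat[k0]), float(vlon[k0])

    sigma2, theta, rho = config.bm_rate, config.ou_strength, config.jump_rate
    max_step = 0.1  # time discretization of the nonlinear attraction

    def walk(lat: float, lon: float, length: float) -> tuple[float, float]:
        if sigma2 == 0 or length == 0:
            return lat, lon
        n_steps = max(1, int(np.ceil(length / max_step)))
        dt = length / n_steps
        if theta > 0:
            decay = float(np.exp(-theta * dt))
            sd = float(np.sqrt(sigma2 * (1 - decay**2) / (2 * theta)))
        else:
            decay = 1.0
            sd = float(np.sqrt(sigma2 * dt))
        for _ in range(n_steps):
            if rho > 0 and rng.random() < -np.expm1(-rho * dt):
                # colonize another valley, preferring nearby ones
                d = distances.haversine_km(lat, lon, vlat, vlon)
                w = np.exp(-d / config.jump_scale_km)
                w /= w.sum()
                target = int(np.searchsorted(np.cumsum(w), rng.random()))
                lat = float(vlat[target] + rng.normal(0.0, config.landing_scatter))
                lon = float(vlon[target] + rng.normal(0.0, config.landing_scatter))
            nearest = int(
                np.argmin(distances.haversine_km(lat, lon, vlat, vlon))
            )
            mu_lat, mu_lon = vlat[nearest], vlon[nearest]
            lat = mu_lat + (lat - mu_lat) * decay + rng.normal(0.0, sd)
            lon = mu_lon + (lon - mu_lon) * decay + rng.normal(0.0, sd)
            lat = float(np.clip(lat, -90, 90))
        return lat, float(lon)

    coords: dict[int, tuple[float, float]] = {id(tree.root): (root_lat, root_lon)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        plat, plon = coords[id(node.parent)]
        coords[id(node)] = walk(plat, plon, node.length)
    rows = []
    tips = tree.tips()
    for tip in tips:
        lat, lon = coords[id(tip)]
        d = distances.haversine_km(lat, lon, clat, clon)
        region = names[int(np.argmin(d))]
        climate = (
            config.climate_intercept
            + config.climate_slope * lat
            + rng.normal(0.0, config.climate_noise)
        )
        year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
        rows.append((tip.label, lat, lon, region, climate, year))
    frame = pd.DataFrame(
        rows, columns=["id", "latitude", "longitude", "region", "climate", "year"]
    ).set_index("id")
    return SampleTable(frame, regions=config.region_names)


def annotate_region_clades(
    tree: Tree, samples: SampleTable, min_size: int = 2
) -> Tree:
    """Label maximal monophyletic internal nodes whose tips share one region.

    Produces the clade-labelled reference tree the origin-assignment rule
    operates on (cf. the known 'Himalayan clades' of the real reference).
    """
    tree = tree.copy()
    region_of = samples.frame["region"].to_dict()
    below = tree.tipset_below()
    regions: dict[int, str | None] = {}
    for node in tree.postorder():
        tipset = below[node]
        regs = {region_of[t] for t in tipset if t in region_of}
        regions[id(node)] = regs.pop() if len(regs) == 1 else None
    for node in tree.preorder():
        if node.is_leaf or node is tree.root:
            continue
        reg = regions[id(node)]
        parent_reg = regions[id(node.parent)]
        if reg is not None and parent_reg is None and len(below[node]) >= min_size:
            node.clade_label = reg
    return tree


# ------------------------------------------------------------ parasite tree
def simulate_parasite_system(
    host_tree: Tree, config: SimConfig, seed: int | None = None
) -> tuple[Tree, AssociationMatrix]:
    """Parasite tree tracking the host tree with occasional host switches.

    The parasite tree starts as a copy of the host topology. Each host
    cladogenesis event (internal node, oldest first, root excluded) triggers
    with probability ``p_switch`` a host switch: one daughter parasite
    lineage is detached and re-grafted, at the same time point, onto a
    uniformly chosen parasite lineage alive then. Switches therefore erase
    recent co-divergence first while the association stays one-to-one.
    Branch lengths are finally scaled by ``parasite_scale``.
    """
    if not 0 <= config.p_switch <= 1:
        raise ConfigError("p_switch must lie in [0, 1]")
    rng = np.random.default_rng(
        derive_seed(config.seed, "parasite") if seed is None else seed
    )
    tree = host_tree.copy()
    ages = {id(n): a for n, a in tree.node_ages().items()}
    nodes = {id(n): n for n in tree.preorder()}
    root_holder = [tree.root]

    events = sorted(
        (n for n in tree.preorder() if not n.is_leaf and n is not tree.root),
        key=lambda n: (-ages[id(n)], min(_tip_labels_below(n))),
    )
    for node in events:
        if not _in_tree(node, root_holder[0]):
            continue
        if rng.random() >= config.p_switch:
            continue
        t = ages[id(node)]
        daughter = node.children[int(rng.integers(len(node.children)))]
        _spr_move(root_holder, node, daughter, t, ages, rng)

    root = root_holder[0]
    for n in _postorder(root):
        n.length *= config.parasite_scale
    root.length = 0.0
    parasite = Tree(root)
    labels = sorted(parasite.tip_labels)
    assoc = AssociationMatrix(labels, labels, np.eye(len(labels), dtype=int))
    return parasite, assoc


def _tip_labels_below(node: TreeNode) -> list[str]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.label)
        else:
            stack.extend(n.children)
    return out


def _in_tree(node: TreeNode, root: TreeNode) -> bool:
    while node.parent is not None:
        node = node.parent
    return node is root


def _spr_move(root_holder, node, daughter, t, ages, rng):
    """Prune ``daughter`` (a child of ``node``) and regraft at age ``t``."""
    root = root_holder[0]
    node.children.remove(daughter)
    daughter.parent = None
    # suppress the now-unary node
    other = node.children[0]
    if node.parent is None:
        other.parent = None
        other.length = 0.0
        root = other
    else:
        other.length += node.length
        other.parent = node.parent
        node.parent.children[node.parent.children.index(node)] = other

    # candidate regraft edges: those alive at age t
    candidates = []
    stack = [root]
    while stack:
        n = stack.pop()
        if n.parent is not None and ages[id(n)] <= t <= ages[id(n.parent)]:
            candidates.append(n)
        stack.extend(n.children)
    candidates.sort(key=lambda n: min(_tip_labels_below(n)))

    if candidates:
        target = candidates[int(rng.integers(len(candidates)))]
        parent = target.parent
        mid = TreeNode(None, ages[id(parent)] - t)
        ages[id(mid)] = t
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        target.length = t - ages[id(target)]
        mid.add_child(target)
        daughter.length = t - ages[id(daughter)]
        mid.add_child(daughter)
    else:
        # regraft above the current root (recreates a root at age t)
        mid = TreeNode(None, 0.0)
        ages[id(mid)] = t
        root.length = t - ages[id(root)]
        mid.add_child(root)
        daughter.length = t - ages[id(daughter)]
        mid.add_child(daughter)
        root = mid
    root_holder[0] = root


# ----------------------------------------------------------------- sequences
def calibrate_rate_scaler(
    tree: Tree, config: SimConfig, model: SubstitutionModel | None = None
) -> float:
    """Bisection for the global rate scaler so the *expected* mean pairwise
    p-distance equals ``target_divergence``."""
    model = model or config.substitution_model()
    pat = distances.patristic_matrix(tree).condensed()
    target = config.target_divergence
    lo, hi = 1e-8, 1.0
    while float(np.mean(model.expected_p_distance(hi * pat))) < target:
        hi *= 2.0
        if hi > 1e6:
            raise SimulationError("cannot reach target divergence: tree too shallow")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(np.mean(model.expected_p_distance(mid * pat))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_sequences(
    tree: Tree,
    config: SimConfig,
    seed: int | None = None,
    rate_scaler: float | None = None,
) -> MultiLocusAlignment:
    """Evolve i.i.d. sites per locus down the tree under JC69/HKY85.

    The global rate scaler is calibrated (bisection on the closed-form
    expected p-distance) so realized mean pairwise divergence lands within a
    few tenths of a percent of the target.
    """
    model = config.substitution_model()
    rng = np.random.default_rng(
        derive_seed(config.seed, "sequences") if seed is None else seed
    )
    if rate_scaler is None:
        rate_scaler = calibrate_rate_scaler(tree, config, model)
    mults = (
        np.asarray(config.locus_rate_multipliers, dtype=float)
        if config.locus_rate_multipliers is not None
        else np.ones(config.n_loci)
    )
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    data: dict[str, dict[str, str]] = {}
    for locus, mult in zip(config.locus_names, mults):
        n = config.locus_length
        states: dict[int, np.ndarray] = {
            id(tree.root): model.stationary_sample(n, rng)
        }
        seqs: dict[str, str] = {}
        for node in tree.preorder():
            if node is not tree.root:
                parent_states = states[id(node.parent)]
                t = rate_scaler * mult * node.length
                if t > 0:
                    P = model.transition_matrix(t)
                    cum = np.cumsum(P, axis=1)
                    u = rng.random(n)
                    child = (u[:, None] > cum[parent_states]).sum(axis=1)
                else:
                    child = parent_states.copy()
                states[id(node)] = child
            if node.is_leaf:
                seqs[node.label] = base_arr[states[id(node)]].tobytes().decode()
        data[locus] = seqs
    return MultiLocusAlignment(config.locus_names, data)


def apply_locus_dropout(
    alignment: MultiLocusAlignment, config: SimConfig, seed: int | None = None
) -> MultiLocusAlignment:
    """Independently drop each sample-locus pair with probability ``dropout``;
    every sample always retains at least one locus."""
    rng = np.random.default_rng(
        derive_seed(config.seed, "dropout") if seed is None else seed
    )
    if config.dropout == 0:
        return alignment
    samples = alignment.samples
    loci = alignment.loci
    keep = rng.random((len(samples), len(loci))) >= config.dropout
    for i in range(len(samples)):
        if not keep[i].any():
            keep[i, int(rng.integers(len(loci)))] = True
    data: dict[str, dict[str, str]] = {l: {} for l in loci}
    for j, locus in enumerate(loci):
        seqs = alignment.data[locus]
        for i, sid in enumerate(samples):
            if sid in seqs and keep[i, j]:
                data[locus][sid] = seqs[sid]
    return MultiLocusAlignment(loci, data)


def mean_pairwise_distance(alignment: MultiLocusAlignment) -> float:
    return float(np.mean(distances.genetic_distance(alignment).condensed()))


# -------------------------------------------------------------------- bundle
@dataclass
class Bundle:
    """One simulated study: everything the downstream pipeline consumes.

    ``host_tree`` carries time-unit branch lengths (for time slices, range
    models and the parasite system); ``host_molecular_tree`` is the same
    topology with branch lengths in expected substitutions/site — the analog
    of the ML reference tree a real analysis would estimate, and the tree
    placement must use.
    """

    config: SimConfig
    host_tree: Tree
    samples: SampleTable
    parasite_tree: Tree
    association: AssociationMatrix
    alignment: MultiLocusAlignment  # after dropout
    full_alignment: MultiLocusAlignment
    parasite_alignment: MultiLocusAlignment
    labelled_tree: Tree  # molecular host tree with region clade labels
    host_molecular_tree: Tree
    rate_scaler: float


def simulate_bundle(config: SimConfig) -> Bundle:
    host = simulate_host_tree(config)
    samples = simulate_geography(host, config)
    parasite, assoc = simulate_parasite_system(host, config)
    scaler = calibrate_rate_scaler(host, config)
    full = simulate_sequences(host, config, rate_scaler=scaler)
    aln = apply_locus_dropout(full, config)
    # one ITS-like locus on the parasite tree, same per-unit rate as the host
    par_cfg = replace(config, n_loci=1, locus_length=600)
    par_aln = simulate_sequences(
        parasite,
        par_cfg,
        seed=derive_seed(config.seed, "parasite_sequences"),
        rate_scaler=scaler,
    )
    molecular = host.scaled(scaler)
    labelled = annotate_region_clades(molecular, samples)
    return Bundle(
        config=config,
        host_tree=host,
        samples=samples,
        parasite_tree=parasite,
        association=assoc,
        alignment=aln,
        full_alignment=full,
        parasite_alignment=par_aln,
        labelled_tree=labelled,
        host_molecular_tree=molecular,
        rate_scaler=scaler,
    )


def write_bundle(bundle: Bundle, directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": directory / "tree.nwk",
        "molecular_tree": directory / "tree_molecular.nwk",
        "labelled_tree": directory / "tree_labelled.nwk",
        "parasite": directory / "parasite.nwk",
        "assoc": directory / "assoc.csv",
        "samples": directory / "samples.csv",
    }
    paths["tree"].write_text(write_newick(bundle.host_tree) + "\n")
    paths["molecular_tree"].write_text(write_newick(bundle.host_molecular_tree) + "\n")
    paths["labelled_tree"].write_text(write_newick(bundle.labelled_tree) + "\n")
    paths["parasite"].write_text(write_newick(bundle.parasite_tree) + "\n")
    bundle.association.to_csv(paths["assoc"])
    bundle.samples.to_csv(paths["samples"])
    locus_paths = write_multilocus_fasta(bundle.alignment, directory / "loci")
    paths.update({f"locus:{k}": v for k, v in locus_paths.items()})
    return paths
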