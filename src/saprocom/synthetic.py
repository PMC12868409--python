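"""Synthetic deadwood-community generator with known ground truth.

Emulates the structure of a 12-year log-exposure experiment: 52 logs
(10 beech, 10 fir and 10 mixed beech-fir plots from one experiment, 12
spruce plots exposed one year later from a second), calendar years
2013-2024 with no sampling in 2020, a ~300-species beetle pool with a
birth-death phylogeny, Brownian-motion continuous traits and
Markov-evolved categorical traits (host-tree association, feeding
type, ...).

Emergence counts follow a resource-pulse model: the expected count of
species s on log l in exposure year t is

    lambda = exp(beta0) * host(s, l) * exp(-delta * t)
             * exp(-(t - mu_s)^2 / (2 sigma_s^2)) * filter(s, t)

where ``host`` penalizes host-tree mismatch, the Gaussian kernel is the
species' temporal niche (abundance-weighted mean mu_s and breadth
sigma_s are therefore known analytically), and ``filter`` down-weights
species far from an early-specialist optimum during the first
``early_years`` years, producing the trait-clustered (low SES-MPD)
early assemblages of a strongly filtered community.  Counts are
negative-binomial with dispersion theta.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, asdict

import dendropy
import numpy as np
import pandas as pd

from .data_model import CommunityTable, SurveyDesign
from .phylo import cophenetic_distance, tip_labels
from .traits import CATEGORICAL, CONTINUOUS, TraitSchema, gower_distance

__all__ = ["SimulationConfig", "Truth", "simulate_phylogeny", "simulate_traits",
           "simulate_emergence", "simulate_dataset", "default_schema"]

MORPHOLOGICAL = ("body_length", "body_width", "body_roundness", "head_length",
                 "wing_length", "wing_aspect", "wing_load", "leg_length",
                 "antenna_length", "eye_length", "hairiness",
                 "mandibular_aspect", "colour")
ECOLOGICAL = {
    "decay_niche": ("early", "mid", "late"),
    "wood_diameter_niche": ("small", "medium", "large"),
    "feeding_type": ("xylophagous", "mycetophagous", "predatory"),
    "host_tree": ("conifer", "broadleaf", "both"),
}


def default_schema() -> TraitSchema:
    """Schema of the generated trait table (13 continuous + 4 categorical)."""
    types = {t: CONTINUOUS for t in MORPHOLOGICAL}
    types.update({t: CATEGORICAL for t in ECOLOGICAL})
    return TraitSchema(
        types=types,
        standardize_by_body_length=("head_length", "wing_length", "leg_length",
                                    "antenna_length", "eye_length"),
        log_transform=("body_length",),
    )


@dataclass
class SimulationConfig:
    """Generator settings; the defaults are the study conditions.

    decay_rate is the per-year decline of log expected abundance (the
    resource pulse); early_filter_strength gamma scales the squared
    distance to the early-specialist optimum (gamma = 0 switches trait
    filtering off); host_penalty is the log-scale penalty for emerging
    from a non-host tree species.  Niche centres mu_s are exponential
    with mean ``niche_center_scale`` (an early-skewed arrival
    distribution) and breadths are sigma_s = niche_breadth_base +
    niche_breadth_slope * mu_s, so early species have narrow temporal
    niches.
    """

    n_species: int = 297
    n_years: int = 12
    paper_design: bool = True
    n_logs_per_tree: int = 10          # used when paper_design is False
    decay_rate: float = 0.35
    early_filter_strength: float = 4.0
    early_years: int = 3
    filter_mode: str = "traits"        # 'traits' | 'phylogeny' | 'none'
    filter_traits: tuple[str, ...] | None = None  # None = all schema traits
    niche_center_scale: float = 3.0
    niche_breadth_base: float = 0.6
    niche_breadth_slope: float = 0.25
    flat_niches: bool = False
    host_penalty: float = 4.0
    host_probs: tuple[float, float, float] = (0.4, 0.35, 0.25)  # conifer/broadleaf/both
    baseline_log_abundance: float = 1.6
    theta: float = 1.5
    bm_rate: float = 1.0
    trait_correlation: float = 0.3  # shared-factor loading of continuous traits
    trait_noise: float = 0.0   # sd of iid (non-phylogenetic) trait component
    markov_rate: float = 0.7
    first_calendar_year: int = 2013
    missing_calendar_years: tuple[int, ...] = (2020,)

    def __post_init__(self):
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.early_filter_strength < 0:
            raise ValueError("early_filter_strength must be >= 0")
        for name in ("decay_rate", "niche_center_scale", "niche_breadth_base",
                     "niche_breadth_slope", "host_penalty", "theta", "bm_rate",
                     "markov_rate"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.filter_mode not in ("traits", "phylogeny", "none"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")


@dataclass
class Truth:
    """Ground-truth parameters behind one simulated data set."""

    mu: dict[str, float]
    sigma: dict[str, float]
    decay_rate: float
    early_filter_strength: float
    early_years: int
    filter_mode: str
    anchor_species: str | None
    filter_distance: dict[str, float]
    host_penalty: float
    baseline_log_abundance: float
    theta: float
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def simulate_phylogeny(n_species: int, seed: int) -> dendropy.Tree:
    """Rooted binary birth-death tree with ``n_species`` uniquely labelled tips."""
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = treesim.birth_death_tree(birth_rate=1.0, death_rate=0.0,
                                    num_extant_tips=n_species, rng=rng)
    width = max(4, len(str(n_species)))
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                    key=lambda lf: lf.taxon.label)):
        leaf.taxon.label = f"sp{i + 1:0{width}d}"
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


def _branching_order(tree: dendropy.Tree):
    for node in tree.preorder_node_iter():
        yield node


def simulate_traits(tree: dendropy.Tree, config: SimulationConfig,
                    seed: int) -> tuple[pd.DataFrame, TraitSchema]:
    """Evolve the trait table along the tree.

    Continuous traits follow Brownian motion (variance ``bm_rate`` per
    unit branch length; body length is exponentiated to keep it
    positive).  Categorical traits follow a jump process: along a branch
    of length t the state is redrawn from the root distribution with
    probability 1 - exp(-markov_rate * t), so higher rates erase
    phylogenetic signal.
    """
    rng = np.random.default_rng(seed)
    schema = default_schema()
    labels = tip_labels(tree)
    cont_names = list(MORPHOLOGICAL)
    values: dict[int, np.ndarray] = {}
    states: dict[int, dict[str, str]] = {}
    root_states = {}
    for name, levels in ECOLOGICAL.items():
        probs = (np.asarray(config.host_probs, float) if name == "host_tree"
                 else np.full(len(levels), 1.0 / len(levels)))
        probs = probs / probs.sum()
        root_states[name] = (levels, probs)
    for node in _branching_order(tree):
        if node.parent_node is None:
            values[id(node)] = np.zeros(len(cont_names))
            states[id(node)] = {
                name: levels[rng.choice(len(levels), p=probs)]
                for name, (levels, probs) in root_states.items()}
            continue
        t = node.edge.length or 0.0
        sd = np.sqrt(max(config.bm_rate * t, 0.0))
        # a shared size-like factor correlates the morphological traits,
        # as in real beetle morphology where most lengths scale together
        c = np.clip(config.trait_correlation, 0.0, 1.0)
        shared = rng.normal(0.0, sd)
        own = rng.normal(0.0, sd, size=len(cont_names))
        step = np.sqrt(c) * shared + np.sqrt(1.0 - c) * own
        values[id(node)] = values[id(node.parent_node)] + step
        st = dict(states[id(node.parent_node)])
        p_jump = 1.0 - np.exp(-config.markov_rate * t)
        for name, (levels, probs) in root_states.items():
            if rng.random() < p_jump:
                st[name] = levels[rng.choice(len(levels), p=probs)]
        states[id(node)] = st
    rows = {}
    for leaf in tree.leaf_node_iter():
        lab = leaf.taxon.label
        tip = values[id(leaf)]
        if config.trait_noise > 0:
            # species-specific component independent of the tree: mixing it in
            # dilutes the phylogenetic signal BM alone always carries
            c = np.clip(config.trait_correlation, 0.0, 1.0)
            shared = rng.normal(0.0, config.trait_noise)
            own = rng.normal(0.0, config.trait_noise, size=len(cont_names))
            tip = tip + np.sqrt(c) * shared + np.sqrt(1.0 - c) * own
        row = dict(zip(cont_names, tip))
        # linear measurements scale multiplicatively with body size: raw
        # lengths are strongly size-correlated while the size-corrected
        # ratios stay nearly independent (which is why the analysis
        # standardizes them by body length before the collinearity check)
        body = float(np.exp(0.5 * row["body_length"] + 1.0))
        row["body_length"] = body
        for t in ("head_length", "wing_length", "leg_length",
                  "antenna_length", "eye_length", "body_width"):
            row[t] = body * float(np.exp(0.35 * row[t]))
        row.update(states[id(leaf)])
        rows[lab] = row
    table = pd.DataFrame.from_dict(rows, orient="index").loc[sorted(labels)]
    table.index.name = "species_id"
    return table, schema


def _make_design(config: SimulationConfig, rng: np.random.Generator) -> SurveyDesign:
    y0 = config.first_calendar_year
    rows = []

    def add_log(idx, tree_sp, plot_id, E, N, start):
        rows.append({"log_id": f"log{idx:03d}", "tree_species": tree_sp,
                     "plot_id": plot_id, "E": E, "N": N, "exposure_start": start})

    idx = 1
    if config.paper_design:
        # 10 beech, 10 fir, 10 mixed beech-fir plots; 12 spruce plots
        plots = (["beech"] * 10 + ["fir"] * 10 + ["mixed"] * 10 + ["spruce"] * 12)
        for p, kind in enumerate(plots):
            E, N = rng.uniform(0, 2000, size=2)
            plot_id = f"plot{p + 1:02d}"
            if kind == "mixed":
                for sp in ("beech", "fir"):
                    add_log(idx, sp, plot_id, E + rng.uniform(-5, 5),
                            N + rng.uniform(-5, 5), y0 - 1)
                    idx += 1
            elif kind == "spruce":
                add_log(idx, "spruce", plot_id, E, N, y0)
                idx += 1
            else:
                add_log(idx, kind, plot_id, E, N, y0 - 1)
                idx += 1
    else:
        p = 1
        for sp in ("beech", "fir", "spruce"):
            start = y0 if sp == "spruce" else y0 - 1
            for _ in range(config.n_logs_per_tree):
                E, N = rng.uniform(0, 2000, size=2)
                add_log(idx, sp, f"plot{p:02d}", E, N, start)
                idx += 1
                p += 1
    years = tuple(y for y in range(y0, y0 + config.n_years)
                  if y not in config.missing_calendar_years)
    # a declared gap only makes sense strictly inside the sampled span
    missing = frozenset(y for y in config.missing_calendar_years
                        if years and min(years) < y < max(years))
    return SurveyDesign(logs=pd.DataFrame(rows), sampling_years=years,
                        missing_years=missing)


def _filter_distance(tree, traits, schema, config,
                     rng) -> tuple[str | None, pd.Series]:
    """Squared-distance basis of the early-colonizer filter, in [0, 1]."""
    species = sorted(traits.index)
    if config.filter_mode == "none" or config.early_filter_strength == 0:
        return None, pd.Series(0.0, index=species)
    # anchor the optimum at a conifer specialist when one exists
    conifer = [s for s in species if traits.loc[s, "host_tree"] == "conifer"]
    anchor = (conifer or species)[int(rng.integers(len(conifer or species)))]
    if config.filter_mode == "traits":
        sub_schema = schema
        if config.filter_traits is not None:
            types = {t: schema.types[t] for t in config.filter_traits}
            sub_schema = TraitSchema(types=types)
        D = gower_distance(traits, sub_schema)
    else:  # phylogeny
        D = cophenetic_distance(tree, species)
    # normalize to [0, 1] so gamma means the same thing in both modes
    d = D.loc[:, anchor] / max(float(D.loc[:, anchor].max()), 1e-300)
    return anchor, d.reindex(species)


_HOST_MATCH = {
    "conifer": {"spruce", "fir"},
    "broadleaf": {"beech"},
    "both": {"spruce", "fir", "beech"},
}


def simulate_emergence(tree: dendropy.Tree, traits: pd.DataFrame,
                       schema: TraitSchema, config: SimulationConfig,
                       seed: int) -> tuple[SurveyDesign, CommunityTable, Truth]:
    """Draw the emergence records for one realization of the experiment."""
    rng = np.random.default_rng(seed)
    design = _make_design(config, rng)
    species = sorted(traits.index)
    mu = rng.exponential(config.niche_center_scale, size=len(species))
    mu = np.clip(mu, 0.0, config.n_years)
    sigma = config.niche_breadth_base + config.niche_breadth_slope * mu
    anchor, fdist = _filter_distance(tree, traits, schema, config, rng)
    host = traits["host_tree"].reindex(species)

    records = []
    for _, log in design.logs.iterrows():
        start = int(log["exposure_start"])
        tsp = log["tree_species"]
        match = np.array([tsp in _HOST_MATCH[h] for h in host])
        host_term = np.where(match, 0.0, -config.host_penalty)
        for cal in design.sampling_years:
            t = cal - start
            if t < 0:
                continue
            eta = (config.baseline_log_abundance + host_term
                   - config.decay_rate * t)
            if not config.flat_niches:
                eta = eta - (t - mu) ** 2 / (2.0 * sigma ** 2)
            if config.early_filter_strength > 0 and t <= config.early_years:
                eta = eta - config.early_filter_strength * fdist.to_numpy() ** 2
            lam = np.exp(eta)
            p = config.theta / (config.theta + lam)
            counts = rng.negative_binomial(config.theta, p)
            nz = np.nonzero(counts)[0]
            for i in nz:
                records.append((log["log_id"], t, species[i], int(counts[i])))
    table = CommunityTable(pd.DataFrame(records, columns=list(CommunityTable.COLUMNS)))
    truth = Truth(
        mu=dict(zip(species, map(float, mu))),
        sigma=dict(zip(species, map(float, sigma))),
        decay_rate=config.decay_rate,
        early_filter_strength=config.early_filter_strength,
        early_years=config.early_years,
        filter_mode=config.filter_mode,
        anchor_species=anchor,
        filter_distance=dict(zip(species, map(float, fdist))),
        host_penalty=config.host_penalty,
        baseline_log_abundance=config.baseline_log_abundance,
        theta=config.theta,
        seed=int(seed),
    )
    return design, table, truth


def simulate_dataset(config: SimulationConfig, seed: int):
    """Phylogeny + traits + design + emergence in one call.

    Returns ``(tree, traits, schema, design, community, truth)``; the
    three stages use sub-seeds derived from ``seed`` so each stage is
    individually reproducible.
    """
    ss = np.random.SeedSequence(seed)
    s_tree, s_traits, s_emerge = (int(s.generate_state(1)[0] % (2**31 - 1))
                                  for s in ss.spawn(3))
    tree = simulate_phylogeny(config.n_species, s_tree)
    traits, schema = simulate_traits(tree, config, s_traits)
    design, community, truth = simulate_emergence(tree, traits, schema, config,
                                                  s_emerge)
    return tree, traits, schema, design, community, truth
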