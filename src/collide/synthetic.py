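"""Synthetic study generator: phylogeny sample, trait table, abundances,
checklists, collisions and light-scored nights with known ground-truth
effects, so every pipeline stage is testable offline.

All randomness flows from a single seed; identical configurations produce
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data_model import (
    ChecklistRecord,
    CollisionRecord,
    NightRecord,
    SpeciesTraits,
    write_records,
)
from .phylo import Phylogeny, parse_newick
from .tallies import DEFAULT_WINDOWS, SeasonWindows

__all__ = ["ScenarioConfig", "SimulatedStudy", "simulate_trees", "simulate_traits", "simulate_observations", "generate_scenario", "write_scenario"]


@dataclass
class ScenarioConfig:
    """All knobs of one synthetic study.  Defaults are sized to the real
    study: 93 species, two seasons per year, uniform light scores 1-17."""

    n_species: int = 93
    tree_model: str = "yule"  # yule | birth_death
    birth_rate: float = 1.0
    death_rate: float = 0.3  # used by birth_death only
    n_trees: int = 50
    tree_age_jitter: float = 0.1
    tree_nni_moves: int = 2
    trait_transition_rate: float = 0.7
    habitat_transition_rate: float = 1.0
    stratum_transition_rate: float = 1.0
    root_flight_call: str = "yes"
    pop_lognormal_params: tuple[float, float] = (12.0, 1.0)
    abundance_lognormal_params: tuple[float, float] = (0.0, 1.0)
    n_nonfocal_species: int = 0
    start_year: int = 2000
    n_days_per_season: int = 90
    checklists_per_day: int = 20
    checklist_detection_scale: float = 0.3
    collision_base_rate: float = 0.01
    beta_flightcall: float = 3.0
    beta_habitat_forest: float = 0.0
    beta_habitat_open: float = 0.0
    beta_stratum_upper: float = 0.0
    n_nights: int = 360
    light_score_distribution: tuple[float, ...] = ()
    b_light_yes: float = 0.0
    b_light_no: float = 0.0
    mccormick_fraction: float = 0.6
    city: str = "chicago"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.tree_model not in ("yule", "birth_death"):
            raise ValueError("tree_model must be 'yule' or 'birth_death'")
        if not self.light_score_distribution:
            # uniform over 1..17, zero mass on a fully dark building
            probs = [0.0] + [1.0 / 17] * 17
            self.light_score_distribution = tuple(probs)
        p = np.asarray(self.light_score_distribution, float)
        if p.size != 18 or abs(p.sum() - 1) > 1e-9 or np.any(p < 0):
            raise ValueError("light_score_distribution must be 18 probs summing to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("pop_lognormal_params", "abundance_lognormal_params", "light_score_distribution"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("pop_lognormal_params", "abundance_lognormal_params", "light_score_distribution"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# trees


class _Node:
    __slots__ = ("children", "age", "label", "dead")

    def __init__(self, age: float = 0.0, label: str | None = None):
        self.children: list[_Node] = []
        self.age = age
        self.label = label
        self.dead = False

    def copy(self) -> "_Node":
        n = _Node(self.age, self.label)
        n.children = [c.copy() for c in self.children]
        return n

    def newick(self) -> str:
        return self._nwk(None) + ";"

    def _nwk(self, parent_age: float | None) -> str:
        if self.children:
            inner = ",".join(c._nwk(self.age) for c in self.children)
            s = f"({inner})"
        else:
            s = self.label or ""
        if parent_age is not None:
            s += f":{parent_age - self.age:.10f}"
        return s


def _simulate_base(config: ScenarioConfig, rng: np.random.Generator) -> _Node:
    birth = config.birth_rate
    death = config.death_rate if config.tree_model == "birth_death" else 0.0
    n = config.n_species
    while True:  # retry on total extinction
        t = 0.0
        root = _Node()
        active: list[tuple[_Node, float]] = [(root, 0.0)]  # (node, birth time)
        ok = True
        while len(active) < n:
            k = len(active)
            t += rng.exponential(1.0 / (k * (birth + death)))
            i = int(rng.integers(k))
            node, _ = active.pop(i)
            if rng.random() < birth / (birth + death):
                left, right = _Node(), _Node()
                node.children = [left, right]
                node.age = t  # temporarily stores forward split time
                active.append((left, t))
                active.append((right, t))
            else:
                node.dead = True
                if not active:
                    ok = False
                    break
        if ok:
            break
    T = t + rng.exponential(1.0 / (n * (birth + death)))

    def prune(node: _Node) -> _Node | None:
        if not node.children:
            return None if node.dead else node
        kids = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:  # suppress unifurcation left by an extinct sister
            return kids[0]
        node.children = kids
        return node

    root = prune(root)
    assert root is not None and root.children

    # forward times -> ages above the tips, normalized height 1
    labels = [f"sp{i + 1:03d}" for i in range(n)]
    rng.shuffle(labels)
    li = iter(labels)

    def finalize(node: _Node) -> None:
        if node.children:
            node.age = (T - node.age) / T
            for c in node.children:
                finalize(c)
        else:
            node.age = 0.0
            node.label = next(li)

    finalize(root)
    root.age = 1.0  # absorb the root stem into the first split's height
    return root


def _jitter(node: _Node, config: ScenarioConfig, rng: np.random.Generator) -> None:
    """Multiplicative age noise, root-down, preserving parent > child."""

    def walk(n: _Node, ceiling: float) -> None:
        if not n.children:
            return
        if ceiling is not None:
            floor = _max_tip_depth_below(n)
            prop = n.age * math.exp(config.tree_age_jitter * rng.standard_normal())
            n.age = min(max(prop, floor + 1e-9), ceiling - 1e-9)
        for c in n.children:
            walk(c, n.age)

    walk(node, None)


def _max_tip_depth_below(node: _Node) -> float:
    if not node.children:
        return 0.0
    return max(c.age if c.children else 0.0 for c in node.children)


def _nni(root: _Node, rng: np.random.Generator) -> None:
    # collect (parent, internal child) edges
    edges = []

    def walk(n: _Node) -> None:
        for c in n.children:
            if c.children:
                edges.append((n, c))
            walk(c)

    walk(root)
    if not edges:
        return
    p, v = edges[int(rng.integers(len(edges)))]
    siblings = [c for c in p.children if c is not v]
    if not siblings or not v.children:
        return
    s = siblings[int(rng.integers(len(siblings)))]
    c = v.children[int(rng.integers(len(v.children)))]
    p.children[p.children.index(s)] = c
    v.children[v.children.index(c)] = s
    # restore parent-above-child ages for v
    floor = max((ch.age if ch.children else 0.0) for ch in v.children)
    if v.age <= floor:
        v.age = 0.5 * (floor + p.age)


def simulate_trees(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> list[Phylogeny]:
    """Simulate an ultrametric base tree and a jittered posterior-like
    sample of ``n_trees`` trees around it (tips ``sp001``...)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base = _simulate_base(config, rng)
    trees = []
    for _ in range(config.n_trees):
        t = base.copy()
        for _m in range(config.tree_nni_moves):
            if rng.random() < 0.5:
                _nni(t, rng)
        _jitter(t, config, rng)
        trees.append(parse_newick(t.newick()))
    return trees


# ---------------------------------------------------------------------------
# traits


def _evolve_ctmc(
    tree: Phylogeny,
    states: tuple[str, ...],
    rate: float,
    root_state: str,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Jump-chain simulation of a symmetric CTMC along the tree branches."""
    out: dict[str, str] = {}

    def walk(node, state: str) -> None:
        length = node.edge.length or 0.0
        n_jumps = rng.poisson(rate * length) if rate > 0 and length > 0 else 0
        for _ in range(n_jumps):
            others = [s for s in states if s != state]
            state = others[int(rng.integers(len(others)))]
        if node.is_leaf():
            out[node.taxon.label] = state
        else:
            for child in node.child_nodes():
                walk(child, state)

    root = tree.tree.seed_node
    for child in root.child_nodes():
        walk(child, root_state)
    if root.is_leaf():
        out[root.taxon.label] = root_state
    return out


def simulate_traits(
    tree: Phylogeny, config: ScenarioConfig, rng: np.random.Generator | None = None
) -> list[SpeciesTraits]:
    """Evolve flight call (binary CTMC), habitat and stratum along the tree;
    draw regional population sizes lognormally.  Optional non-focal species
    (diurnal/resident/non-passerine) are appended off-tree."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    fc = _evolve_ctmc(tree, ("yes", "no"), config.trait_transition_rate, config.root_flight_call, rng)
    hab_root = ("forest", "edge", "open")[int(rng.integers(3))]
    hab = _evolve_ctmc(tree, ("forest", "edge", "open"), config.habitat_transition_rate, hab_root, rng)
    strat_root = ("upper", "lower")[int(rng.integers(2))]
    strat = _evolve_ctmc(tree, ("upper", "lower"), config.stratum_transition_rate, strat_root, rng)
    mu, sigma = config.pop_lognormal_params
    traits = []
    for sp in sorted(fc):
        traits.append(
            SpeciesTraits(
                species_id=sp,
                flight_call=fc[sp],
                habitat=hab[sp],
                stratum=strat[sp],
                regional_pop_size=float(np.exp(mu + sigma * rng.standard_normal())),
                migratory_class="nocturnal_passerine",
            )
        )
    other_classes = ("diurnal_passerine", "resident", "nonpasserine")
    for j in range(config.n_nonfocal_species):
        traits.append(
            SpeciesTraits(
                species_id=f"nf{j + 1:03d}",
                flight_call=("yes", "no")[int(rng.integers(2))],
                habitat=("forest", "edge", "open")[int(rng.integers(3))],
                stratum=("upper", "lower")[int(rng.integers(2))],
                regional_pop_size=float(np.exp(mu + sigma * rng.standard_normal())),
                migratory_class=other_classes[j % 3],
            )
        )
    return traits


# ---------------------------------------------------------------------------
# observations


@dataclass
class SimulatedStudy:
    config: ScenarioConfig
    trees: list[Phylogeny]
    traits: list[SpeciesTraits]
    abundance: dict[str, float]
    checklists: list[ChecklistRecord]
    collisions: list[CollisionRecord]
    nights: list[NightRecord]


def _monitoring_dates(config: ScenarioConfig, windows: SeasonWindows) -> list:
    dates = []
    year = config.start_year
    while len(dates) < config.n_nights:
        for season in ("spring", "autumn"):
            dates.extend(windows.dates(season, year)[: config.n_days_per_season])
        year += 1
    return dates[: config.n_nights]


def simulate_observations(
    traits: list[SpeciesTraits],
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    windows: SeasonWindows = DEFAULT_WINDOWS,
) -> tuple[list[ChecklistRecord], list[CollisionRecord], list[NightRecord], dict[str, float]]:
    """Generate checklists, collisions and light-scored nights.

    Checklist detection per day saturates in abundance (complementary-log
    link), reproducing the compression of the presence-based abundance
    index.  Collisions per species-night are Poisson with
    ``log-rate = log(base * abundance) + trait effects + b_light * score``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    species = [t.species_id for t in traits]
    n_sp = len(species)
    a_mu, a_sigma = config.abundance_lognormal_params
    abundance = np.exp(a_mu + a_sigma * rng.standard_normal(n_sp))
    dates = _monitoring_dates(config, windows)
    n_nights = len(dates)

    # light scores
    scores = rng.choice(18, size=n_nights, p=np.asarray(config.light_score_distribution))

    # checklists: Binomial(K, 1 - exp(-scale * abundance)) per species-day
    p_det = 1.0 - np.exp(-config.checklist_detection_scale * abundance)
    k_det = rng.binomial(config.checklists_per_day, p_det, size=(n_nights, n_sp))

    # collisions
    is_yes = np.array([t.flight_call == "yes" for t in traits])
    log_rate = np.log(config.collision_base_rate * abundance)
    log_rate = log_rate + config.beta_flightcall * is_yes
    log_rate = log_rate + config.beta_habitat_forest * np.array(
        [t.habitat == "forest" for t in traits]
    )
    log_rate = log_rate + config.beta_habitat_open * np.array(
        [t.habitat == "open" for t in traits]
    )
    log_rate = log_rate + config.beta_stratum_upper * np.array(
        [t.stratum == "upper" for t in traits]
    )
    b_light = np.where(is_yes, config.b_light_yes, config.b_light_no)
    rates = np.exp(log_rate[None, :] + np.outer(scores, b_light))
    n_coll = rng.poisson(rates)

    checklists: list[ChecklistRecord] = []
    collisions: list[CollisionRecord] = []
    nights: list[NightRecord] = []
    for di, date in enumerate(dates):
        for si in np.flatnonzero(k_det[di]):
            checklists.extend(
                ChecklistRecord(species[si], date, config.city)
                for _ in range(int(k_det[di, si]))
            )
        per_night = []
        for si in np.flatnonzero(n_coll[di]):
            count = int(n_coll[di, si])
            per_night.append((species[si], count))
            for _ in range(count):
                site = (
                    "mccormick"
                    if rng.random() < config.mccormick_fraction
                    else "downtown"
                )
                collisions.append(CollisionRecord(species[si], date, site, config.city))
        nights.append(NightRecord(date, int(scores[di]), tuple(per_night)))
    return checklists, collisions, nights, dict(zip(species, abundance.tolist()))


def generate_scenario(config: ScenarioConfig) -> SimulatedStudy:
    """Run the full generator from a single seed."""
    rng = np.random.default_rng(config.seed)
    trees = simulate_trees(config, rng)
    traits = simulate_traits(trees[0], config, rng)
    checklists, collisions, nights, abundance = simulate_observations(traits, config, rng)
    return SimulatedStudy(config, trees, traits, abundance, checklists, collisions, nights)


def write_scenario(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write the study in the exact formats the analysis pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_records(study.collisions, "collision", outdir / "collisions.csv")
    write_records(study.checklists, "checklist", outdir / "checklists.csv")
    write_records(study.traits, "traits", outdir / "traits.csv")
    write_records(study.nights, "nights", outdir / "nights.csv")
    with (outdir / "trees.nwk").open("w", encoding="utf-8") as fh:
        for tree in study.trees:
            fh.write(tree.to_newick() + "\n")
    prov = {
        "config": study.config.to_dict(),
        "config_hash": study.config.config_hash(),
        "seed": study.config.seed,
    }
    with (outdir / "provenance.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(prov, fh, sort_keys=True)
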