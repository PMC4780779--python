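"""Synthetic trees, states, traits, climate grids and occurrence clouds.

Every pipeline stage is testable without external data: the generator emits
exactly the formats the pipeline reads (occurrence CSV, ESRI ASCII grids,
newick, backbone spec, assignment CSV) together with a machine-readable truth
record.

The emulated structure mirrors the study system: a pure-birth phylogeny whose
C4 state is painted onto a few whole clades (state changes are
clade-restricted, not i.i.d. per tip — the regime in which ordinary least
squares is anticonservative and PGLS is needed); species niche limits that are
phylogenetically correlated traits with a known C4 − C3 shift injected into
the warm-limit of the warmest-quarter temperature; and occurrence clouds drawn
uniformly from the grid cells inside each species' climatic interval.

Geometry: one record carries a single (lon, lat), so the three climate
variables share two spatial axes. MTWQ increases with latitude and MTCQ
decreases with it (hence MTCQ limits are affine in the MTWQ limit traits,
with known implied effects recorded in the truth), while AI varies with
longitude, independently of the temperatures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import optimize, stats

from .backbone_tree import (
    BackboneClade,
    BackboneSpec,
    BranchLengthScheme,
    collapse_to_backbone,
    graft_taxa,
    write_assignments,
    write_backbone_spec,
    write_newick,
)
from .occurrence_climate import ClimateGrid, write_ascii_grid
from .pgls_core import CorrelationModel, Family, TreeData, transform_vcv

VARIABLES = ("AI", "MTWQ", "MTCQ")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Trees and states


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed=None) -> dendropy.Tree:
    """Pure-birth tree with exponential waiting times; tips labelled sp0001…

    The root splits at time 0; with k extant lineages the next split waits
    Exp(k·birth_rate); after the (n−1)-th split one further Exp(n·birth_rate)
    interval is appended, so all tips are contemporaneous (ultrametric).
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = _rng(seed)
    tree = dendropy.Tree()
    tree.is_rooted = True
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = [
        (tree.seed_node, 0.0),
        (tree.seed_node, 0.0),
    ]
    # each entry: (parent node, birth time of this pending lineage)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        parent, t0 = active.pop(i)
        node = parent.new_child(edge_length=t - t0)
        active.append((node, t))
        active.append((node, t))
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    counter = 0
    for parent, t0 in active:
        counter += 1
        leaf = parent.new_child(edge_length=t - t0)
        leaf.taxon = tree.taxon_namespace.require_taxon(label=f"sp{counter:04d}")
    return tree


def _min_state_changes(tree: dendropy.Tree, flipped: frozenset[str]) -> int:
    """Minimum binary state changes on the tree (unit-cost DP over polytomies)."""
    INF = 10**9
    cost: dict[int, tuple[int, int]] = {}  # node id -> (cost if C3, cost if C4)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            is_c4 = node.taxon.label in flipped
            cost[id(node)] = (INF, 0) if is_c4 else (0, INF)
        else:
            c3 = c4 = 0
            for child in node.child_nodes():
                k3, k4 = cost[id(child)]
                c3 += min(k3, k4 + 1)
                c4 += min(k4, k3 + 1)
            cost[id(node)] = (c3, c4)
    return min(cost[id(tree.seed_node)])


def assign_states_by_clades(
    tree: dendropy.Tree, n_transitions: int, seed=None, max_attempts: int = 500
) -> tuple[dict[str, str], list[frozenset[str]]]:
    """Paint C4 onto ``n_transitions`` non-nested clades; everything else is C3.

    Returns the per-tip state map and the flipped leaf sets (one per
    transition). The parsimony score of the resulting states on the tree
    equals ``n_transitions`` by construction.
    """
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    n = len(leaves)
    if not 1 <= n_transitions < n / 2:
        raise ValueError("need 1 <= n_transitions < n_tips/2")
    rng = _rng(seed)
    candidates = [
        frozenset(l.taxon.label for l in node.leaf_iter())
        for node in tree.preorder_internal_node_iter()
        if node is not tree.seed_node
    ]
    if len(candidates) < n_transitions:
        raise ValueError("tree has too few internal nodes")
    for _ in range(max_attempts):
        # greedy scan over a shuffled candidate order: much more likely to
        # find n_transitions disjoint clades than an independent uniform draw
        order = rng.permutation(len(candidates))
        sets: list[frozenset[str]] = []
        flipped: frozenset[str] = frozenset()
        for i in order:
            cand = candidates[int(i)]
            if cand & flipped or len(flipped | cand) >= n:
                continue
            sets.append(cand)
            flipped = flipped | cand
            if len(sets) == n_transitions:
                break
        # adjacent picks can let parsimony merge transitions (fully flipped
        # ancestor, or a mostly flipped root), so verify the realised number
        # of state changes before accepting the draw
        if len(sets) == n_transitions and _min_state_changes(tree, flipped) == n_transitions:
            states = {l: ("C4" if l in flipped else "C3") for l in leaves}
            return states, sets
    raise RuntimeError(
        f"could not place {n_transitions} non-nested transitions in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Traits


def simulate_tip_values(
    tree,
    states: Mapping[str, str],
    family: Family,
    theta: float | None,
    beta0: float,
    beta1: float,
    sigma2: float,
    seed=None,
) -> tuple[list[str], np.ndarray]:
    """y = β0 + β1·1[C4] + ε, ε ~ N(0, σ²·C(family, θ)), via Cholesky draw."""
    rng = _rng(seed)
    td = TreeData.ensure(tree)
    ind = np.array([1.0 if states[l] == "C4" else 0.0 for l in td.labels])
    mean = beta0 + beta1 * ind
    if sigma2 == 0:
        return list(td.labels), mean
    C = transform_vcv(td.V, td, CorrelationModel(family, theta))
    L = np.linalg.cholesky(C)
    y = mean + math.sqrt(sigma2) * (L @ rng.standard_normal(td.n))
    return list(td.labels), y


def sigma_for_power(
    tree,
    states: Mapping[str, str],
    beta1: float,
    power: float = 0.97,
    alpha: float = 0.05,
) -> float:
    """Residual scale σ giving analytic GLS power for detecting ``beta1``.

    Uses the exact noncentral-t power of the two-sided β1 test under the
    Brownian structure of the tree: find the noncentrality achieving the
    target, then σ = |β1| / (ncp·√c11) with c11 = [(XᵀV⁻¹X)⁻¹]₁₁.
    """
    if beta1 == 0:
        raise ValueError("power rule needs a nonzero effect")
    td = TreeData.ensure(tree)
    ind = np.array([1.0 if states[l] == "C4" else 0.0 for l in td.labels])
    if ind.min() == ind.max():
        raise ValueError("both states required")
    X = np.column_stack([np.ones(td.n), ind])
    Vi_X = np.linalg.solve(td.V, X)
    c11 = np.linalg.inv(X.T @ Vi_X)[1, 1]
    df = td.n - 2
    tcrit = stats.t.ppf(1 - alpha / 2, df)

    def power_at(ncp: float) -> float:
        # nct can underflow to NaN far in the tails; those terms are 1 and 0.
        upper = float(stats.nct.sf(tcrit, df, ncp))
        lower = float(stats.nct.cdf(-tcrit, df, ncp))
        if math.isnan(upper):
            upper = 1.0
        if math.isnan(lower):
            lower = 0.0
        return upper + lower

    ncp = optimize.brentq(lambda m: power_at(m) - power, 1e-6, 50.0)
    return abs(beta1) / (ncp * math.sqrt(c11))


# ---------------------------------------------------------------------------
# Grids and occurrences


def simulate_climate_grid(
    variable_id: str,
    extent: tuple[float, float, float, int, int],
    gradient_low: float,
    gradient_high: float,
    noise_sd: float = 0.0,
    seed=None,
    axis: str = "lat",
) -> ClimateGrid:
    """Linear-gradient grid: low→high south→north (``axis='lat'``, default)
    or west→east (``axis='lon'``), plus independent cell noise. AI grids are
    clipped at 0."""
    if gradient_low >= gradient_high:
        raise ValueError("gradient_low must be < gradient_high")
    x_ll, y_ll, cell, n_cols, n_rows = extent
    rng = _rng(seed)
    if axis == "lat":
        profile = np.linspace(gradient_high, gradient_low, n_rows)  # row 0 = north
        values = np.tile(profile[:, None], (1, n_cols))
    elif axis == "lon":
        profile = np.linspace(gradient_low, gradient_high, n_cols)
        values = np.tile(profile[None, :], (n_rows, 1))
    else:
        raise ValueError("axis must be 'lat' or 'lon'")
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    if variable_id == "AI":
        values = np.clip(values, 0.0, None)
    return ClimateGrid(
        variable_id=variable_id,
        n_cols=n_cols,
        n_rows=n_rows,
        x_ll=x_ll,
        y_ll=y_ll,
        cell_size=cell,
        nodata_value=-9999.0,
        values=values,
    )


def simulate_occurrences(
    species_id: str,
    niche_interval: tuple[float, float],
    grid: ClimateGrid,
    n_records: int,
    seed=None,
) -> np.ndarray:
    """``n_records`` (lon, lat) points drawn uniformly over the grid cells
    whose value lies in the niche interval, jittered within each cell."""
    a, b = niche_interval
    rng = _rng(seed)
    eligible = np.argwhere((grid.values >= a) & (grid.values <= b))
    if eligible.size == 0:
        raise ValueError(f"species {species_id!r}: no grid cells in [{a}, {b}]")
    idx = rng.integers(len(eligible), size=n_records)
    rows, cols = eligible[idx, 0], eligible[idx, 1]
    u = rng.random(n_records)
    v = rng.random(n_records)
    lon = grid.x_ll + (cols + u) * grid.cell_size
    lat = grid.y_ll + (grid.n_rows - 1 - rows + v) * grid.cell_size
    return np.column_stack([lon, lat])


# ---------------------------------------------------------------------------
# Full scenario


@dataclass
class VariablePlan:
    """Truth plan for one variable's two limit traits."""

    beta0_min: float
    beta0_max: float
    beta1_min: float = 0.0
    beta1_max: float = 0.0
    min_width: float = 0.5  # floor on max − min per species


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic bundle.

    Defaults: an 80-species working phylogeny (40 sequenced + 40 grafted,
    emulating that roughly half the taxa lack sequence data), 4 clade-level
    C3→C4 transitions, 80 records per species, a 1.61 °C C4 shift of the
    MTWQ upper limit (the headline warm-limit contrast magnitude) and no
    injected effect anywhere else, with the residual scale of the
    temperature traits chosen by the analytic power rule (target 0.97, which
    leaves margin for trim attenuation and grid discretisation so realised
    end-to-end power stays above 0.9).
    """

    n_sampled: int = 40
    n_grafted: int = 40
    birth_rate: float = 1.0
    n_transitions: int = 4
    clade_size_max: int = 8
    n_records: int = 80
    mtwq: VariablePlan = field(
        default_factory=lambda: VariablePlan(18.0, 28.0, 0.0, 1.61, 0.5)
    )
    ai: VariablePlan = field(
        default_factory=lambda: VariablePlan(0.4, 1.6, 0.0, 0.0, 0.05)
    )
    mtcq_cold: float = 0.0  # MTCQ at the MTWQ-warm (north) end
    mtcq_warm: float = 22.0  # MTCQ at the MTWQ-cool (south) end
    ai_tip_sd: float = 0.15  # tip sd for the no-effect AI traits
    power_target: float = 0.97
    alpha: float = 0.05
    grid_cells: int = 100
    extent: tuple[float, float, float] = (0.0, 0.0, 0.3)  # x_ll, y_ll, cell
    family: str = "brownian"
    theta: float | None = None


@dataclass
class ScenarioTruth:
    """Everything an end-to-end test needs: generating model and per-species truth."""

    seed: int
    states: dict[str, str]
    n_records: int
    family: str
    theta: float | None
    # per response key ("MTWQ_min", "MTWQ_max", ...): generating β0, β1, σ
    effects: dict[str, dict[str, float]]
    # per species, per variable: attainable [low, high] on the emitted grids
    intervals: dict[str, dict[str, tuple[float, float]]]
    n_transitions: int
    transition_clades: list[list[str]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        d["intervals"] = {
            sp: {var: tuple(iv) for var, iv in per.items()}
            for sp, per in d["intervals"].items()
        }
        return cls(**d)


def _partition_clades(
    tree: dendropy.Tree, max_size: int, min_groups: int = 1
) -> list[list[str]]:
    """Partition the tips into monophyletic groups of at most ``max_size``.

    The collapsed working tree is a star of these groups, so state
    transitions can only be painted onto whole groups; ``min_groups`` lets
    the caller guarantee enough groups that the requested transition count
    is realisable (the parsimony score of k painted groups out of m root
    children is min(k, m − k)).
    """
    nodes: list[dendropy.Node] = []

    def rec(node):
        if len(list(node.leaf_iter())) <= max_size:
            nodes.append(node)
        else:
            for child in node.child_nodes():
                rec(child)

    for child in tree.seed_node.child_nodes():
        rec(child)
    while len(nodes) < min_groups:
        nodes.sort(key=lambda nd: len(list(nd.leaf_iter())))
        big = nodes.pop()
        if big.is_leaf():
            nodes.append(big)
            break  # every group is a single tip; cannot split further
        nodes.extend(big.child_nodes())
    return [[l.taxon.label for l in nd.leaf_iter()] for nd in nodes]


def make_scenario(config: ScenarioConfig, seed: int, out_dir: str | Path) -> ScenarioTruth:
    """Write a complete synthetic bundle and return its truth record.

    Files written to ``out_dir``: occurrences.csv, grid_<VAR>.asc (three),
    tree.nwk (resolved tree of the sequenced species), backbone.txt,
    assignments.csv, truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed)
    cfg = config
    family = Family(cfg.family)

    # --- phylogeny, backbone, grafting -----------------------------------
    source_tree = simulate_yule_tree(cfg.n_sampled, cfg.birth_rate, rng)
    groups = _partition_clades(
        source_tree, cfg.clade_size_max, min_groups=2 * cfg.n_transitions + 1
    )
    spec = BackboneSpec(
        roots=[
            BackboneClade(name=f"K{i + 1:02d}", state="mixed", members=g)
            for i, g in enumerate(groups)
        ]
    )
    working = collapse_to_backbone(source_tree, spec)
    grafted = [f"gsp{i + 1:04d}" for i in range(cfg.n_grafted)]
    assignments = {
        sp: f"K{int(rng.integers(len(groups))) + 1:02d}" for sp in grafted
    }
    truth_tree = graft_taxa(
        working, assignments, BranchLengthScheme.CLADE_MEAN, reference_tree=source_tree
    )
    states, transition_sets = assign_states_by_clades(truth_tree, cfg.n_transitions, rng)
    td = TreeData(truth_tree)

    # --- limit traits ------------------------------------------------------
    if cfg.mtwq.beta1_max or cfg.mtwq.beta1_min:
        ref_beta1 = cfg.mtwq.beta1_max or cfg.mtwq.beta1_min
        sigma_t = sigma_for_power(td, states, ref_beta1, cfg.power_target, cfg.alpha)
    else:
        sigma_t = 1.0 / math.sqrt(td.T)
    sigma_ai = cfg.ai_tip_sd / math.sqrt(td.T)

    def draw(beta0, beta1, sigma):
        _, y = simulate_tip_values(
            td, states, family, cfg.theta, beta0, beta1, sigma**2, rng
        )
        return y

    mtwq_max = draw(cfg.mtwq.beta0_max, cfg.mtwq.beta1_max, sigma_t)
    mtwq_min = draw(cfg.mtwq.beta0_min, cfg.mtwq.beta1_min, sigma_t)
    mtwq_min = np.minimum(mtwq_min, mtwq_max - cfg.mtwq.min_width)
    ai_max = draw(cfg.ai.beta0_max, cfg.ai.beta1_max, sigma_ai)
    ai_min = draw(cfg.ai.beta0_min, cfg.ai.beta1_min, sigma_ai)
    ai_min = np.clip(np.minimum(ai_min, ai_max - cfg.ai.min_width), 0.0, None)
    ai_max = np.maximum(ai_max, ai_min + cfg.ai.min_width)

    # --- grids -------------------------------------------------------------
    x_ll, y_ll, cell = cfg.extent
    n_cells = cfg.grid_cells
    extent5 = (x_ll, y_ll, cell, n_cells, n_cells)
    w_lo = float(mtwq_min.min() - 1.0)
    w_hi = float(mtwq_max.max() + 1.0)
    grid_mtwq = simulate_climate_grid("MTWQ", extent5, w_lo, w_hi, 0.0, rng, axis="lat")
    a_lo = max(0.0, float(ai_min.min() - 0.1))
    a_hi = float(ai_max.max() + 0.1)
    grid_ai = simulate_climate_grid("AI", extent5, a_lo, a_hi, 0.0, rng, axis="lon")
    # MTCQ decreases northward: build the south→north profile and flip it.
    g = simulate_climate_grid("MTCQ", extent5, cfg.mtcq_cold, cfg.mtcq_warm, 0.0, rng, axis="lat")
    grid_mtcq = ClimateGrid(
        "MTCQ", n_cells, n_cells, x_ll, y_ll, cell, -9999.0, g.values[::-1].copy()
    )

    # --- occurrences -------------------------------------------------------
    mtwq_rows = grid_mtwq.values[:, 0]  # value per row (row 0 = north)
    mtcq_rows = grid_mtcq.values[:, 0]
    ai_cols = grid_ai.values[0, :]
    species = list(td.labels)
    intervals: dict[str, dict[str, tuple[float, float]]] = {}
    rows_out = []
    for i, sp in enumerate(species):
        elig_rows = np.flatnonzero(
            (mtwq_rows >= mtwq_min[i]) & (mtwq_rows <= mtwq_max[i])
        )
        if elig_rows.size == 0:  # interval narrower than a cell: take nearest row
            elig_rows = np.array([int(np.argmin(np.abs(mtwq_rows - mtwq_max[i])))])
        elig_cols = np.flatnonzero((ai_cols >= ai_min[i]) & (ai_cols <= ai_max[i]))
        if elig_cols.size == 0:
            elig_cols = np.array([int(np.argmin(np.abs(ai_cols - ai_max[i])))])
        r = elig_rows[rng.integers(elig_rows.size, size=cfg.n_records)]
        cidx = elig_cols[rng.integers(elig_cols.size, size=cfg.n_records)]
        lon = x_ll + (cidx + rng.random(cfg.n_records)) * cell
        lat = y_ll + (n_cells - 1 - r + rng.random(cfg.n_records)) * cell
        for x, y in zip(lon, lat):
            rows_out.append((sp, states[sp], float(x), float(y)))
        intervals[sp] = {
            "MTWQ": (float(mtwq_rows[elig_rows].min()), float(mtwq_rows[elig_rows].max())),
            "MTCQ": (float(mtcq_rows[elig_rows].min()), float(mtcq_rows[elig_rows].max())),
            "AI": (float(ai_cols[elig_cols].min()), float(ai_cols[elig_cols].max())),
        }

    # --- truth record ------------------------------------------------------
    slope = (cfg.mtcq_warm - cfg.mtcq_cold) / (w_hi - w_lo)  # MTCQ per unit MTWQ
    effects = {
        "MTWQ_min": {"beta0": cfg.mtwq.beta0_min, "beta1": cfg.mtwq.beta1_min, "sigma": sigma_t},
        "MTWQ_max": {"beta0": cfg.mtwq.beta0_max, "beta1": cfg.mtwq.beta1_max, "sigma": sigma_t},
        "AI_min": {"beta0": cfg.ai.beta0_min, "beta1": cfg.ai.beta1_min, "sigma": sigma_ai},
        "AI_max": {"beta0": cfg.ai.beta0_max, "beta1": cfg.ai.beta1_max, "sigma": sigma_ai},
        # MTCQ limits are affine images of the MTWQ limit traits
        "MTCQ_min": {
            "beta0": cfg.mtcq_warm - slope * (cfg.mtwq.beta0_max - w_lo),
            "beta1": -slope * cfg.mtwq.beta1_max,
            "sigma": slope * sigma_t,
        },
        "MTCQ_max": {
            "beta0": cfg.mtcq_warm - slope * (cfg.mtwq.beta0_min - w_lo),
            "beta1": -slope * cfg.mtwq.beta1_min,
            "sigma": slope * sigma_t,
        },
    }
    truth = ScenarioTruth(
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        states=states,
        n_records=cfg.n_records,
        family=cfg.family,
        theta=cfg.theta,
        effects=effects,
        intervals=intervals,
        n_transitions=cfg.n_transitions,
        transition_clades=[sorted(s) for s in transition_sets],
    )

    # --- files -------------------------------------------------------------
    import csv

    with open(out / "occurrences.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "state", "lon", "lat"])
        w.writerows(rows_out)
    write_ascii_grid(grid_mtwq, str(out / "grid_MTWQ.asc"))
    write_ascii_grid(grid_mtcq, str(out / "grid_MTCQ.asc"))
    write_ascii_grid(grid_ai, str(out / "grid_AI.asc"))
    with open(out / "tree.nwk", "w", encoding="utf-8") as fh:
        fh.write(write_newick(source_tree))
    write_backbone_spec(spec, str(out / "backbone.txt"))
    write_assignments(assignments, str(out / "assignments.csv"))
    truth.to_json(out / "truth.json")
    return truth
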