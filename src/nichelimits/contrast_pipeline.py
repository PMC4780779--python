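"""End-to-end C3/C4 niche-limit contrasts and the tabular report.

``run_contrasts`` wires the stages together: occurrence ingestion → climate
annotation → record-count filter → trimmed extremes → working phylogeny
(backbone collapse + grafting per branch-length scheme) → five-model PGLS
suite per clade scope × variable × extreme × scheme. The report mirrors the
classic contrast table: best-fitting model, estimated C3 and C4 means, their
difference, and the two-sided p-value, with rows merged across branch-length
schemes when they agree.
"""

from __future__ import annotations

import io
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd

from . import backbone_tree as bt
from . import niche_extremes as ne
from . import occurrence_climate as oc
from . import pgls_core as pg
from .errors import ConfigurationError, ReconciliationError

log = logging.getLogger(__name__)

SCHEME_NUMBER = {
    bt.BranchLengthScheme.EQUAL: 1,
    bt.BranchLengthScheme.GLOBAL_MEAN: 2,
    bt.BranchLengthScheme.CLADE_MEAN: 3,
}
FAMILY_DISPLAY = {
    pg.Family.INDEPENDENT: "None",
    pg.Family.BROWNIAN: "Brownian",
    pg.Family.PAGEL_LAMBDA: "Pagel",
    pg.Family.GRAFEN_RHO: "Grafen",
    pg.Family.ACDC_G: "ACDC",
}
WHOLE_TREE = "all"


@dataclass
class RunConfig:
    occurrences: str
    grids: dict[str, str]  # variable -> .asc path
    tree: str
    backbone_spec: str | None = None
    assignments: str | None = None
    output_dir: str = "."
    clades: list[str] = field(default_factory=list)  # empty = whole tree only
    variables: list[str] = field(default_factory=lambda: ["AI", "MTWQ", "MTCQ"])
    extremes: list[str] = field(default_factory=lambda: ["min", "max"])
    schemes: list[bt.BranchLengthScheme] = field(
        default_factory=lambda: list(bt.BranchLengthScheme)
    )
    trim_fraction: float = 0.05
    min_records: int = 6
    per_variable_filter: bool = True
    method: str = "ML"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        self.schemes = [
            s if isinstance(s, bt.BranchLengthScheme) else bt.BranchLengthScheme(int(s))
            for s in self.schemes
        ]

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        base = path.parent

        def resolve(p):
            return str((base / p).resolve()) if p else None

        raw["occurrences"] = resolve(raw["occurrences"])
        raw["grids"] = {k: resolve(v) for k, v in raw["grids"].items()}
        raw["tree"] = resolve(raw["tree"])
        for key in ("backbone_spec", "assignments"):
            if raw.get(key):
                raw[key] = resolve(raw[key])
        if raw.get("output_dir"):
            raw["output_dir"] = resolve(raw["output_dir"])
        return cls(**raw)

    def write_toml(self, path: str | Path) -> None:
        lines = [
            f'occurrences = "{self.occurrences}"',
            f'tree = "{self.tree}"',
        ]
        if self.backbone_spec:
            lines.append(f'backbone_spec = "{self.backbone_spec}"')
        if self.assignments:
            lines.append(f'assignments = "{self.assignments}"')
        lines += [
            f'output_dir = "{self.output_dir}"',
            f"clades = {self.clades!r}".replace("'", '"'),
            f"variables = {self.variables!r}".replace("'", '"'),
            f"extremes = {self.extremes!r}".replace("'", '"'),
            f"schemes = {[SCHEME_NUMBER[s] for s in self.schemes]}",
            f"trim_fraction = {self.trim_fraction}",
            f"min_records = {self.min_records}",
            f"per_variable_filter = {str(self.per_variable_filter).lower()}",
            f'method = "{self.method}"',
            f"alpha = {self.alpha}",
            f"seed = {self.seed}",
            "",
            "[grids]",
        ]
        for var, p in self.grids.items():
            lines.append(f'{var} = "{p}"')
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class ContrastRow:
    clade: str
    variable: str
    extreme: str  # "min" | "max"
    schemes: str  # e.g. "1, 2, 3"
    best_model: str
    theta: float | None
    mean_c3: float
    mean_c4: float
    difference: float
    p: float
    significant: bool
    agreement: bool


def compute_summaries(config: RunConfig) -> list[ne.SpeciesClimateSummary]:
    """Occurrences + grids → filtered, trimmed per-species climate summaries."""
    records, _ = oc.read_occurrence_table(config.occurrences)
    grids = {}
    for var in config.variables:
        if var not in config.grids:
            raise ConfigurationError(f"no grid configured for variable {var!r}")
        grids[var] = oc.read_ascii_grid(config.grids[var], var)
    samples = oc.attach_climate(records, grids)
    kept = oc.filter_min_records(samples, config.min_records, config.per_variable_filter)
    states: dict[str, str] = {}
    for rec in records:
        prev = states.setdefault(rec.species_id, rec.state)
        if prev != rec.state:
            raise ConfigurationError(
                f"species {rec.species_id!r} has conflicting states {prev}/{rec.state}"
            )
    return ne.summarize_species(kept, states, config.trim_fraction)


def build_working_trees(config: RunConfig):
    """Parse/collapse/graft: one working phylogeny per branch-length scheme."""
    source = bt.parse_newick(config.tree)
    tree = source
    if config.backbone_spec:
        spec = bt.parse_backbone_spec(config.backbone_spec)
        tree = bt.collapse_to_backbone(source, spec)
    assignments = bt.read_assignments(config.assignments) if config.assignments else {}
    return {
        scheme: bt.graft_taxa(tree, assignments, scheme, reference_tree=source)
        for scheme in config.schemes
    }


def _reconcile(tree, summaries):
    """Prune tree leaves without summaries; summary species absent from the tree are fatal."""
    leaf_set = set(bt.leaf_labels(tree))
    summary_set = {s.species_id for s in summaries}
    missing = sorted(summary_set - leaf_set)
    if missing:
        raise ReconciliationError(
            f"{len(missing)} summarized species missing from the working phylogeny: "
            + ", ".join(missing[:10])
            + ("…" if len(missing) > 10 else "")
        )
    extra = leaf_set - summary_set
    if extra:
        log.info("pruning %d tree leaves without climate summaries", len(extra))
        tree.retain_taxa_with_labels(sorted(summary_set))
    return tree


def fit_contrasts(
    summaries: Sequence[ne.SpeciesClimateSummary],
    tree,
    config: RunConfig,
    clade_label: str,
    scheme: bt.BranchLengthScheme,
) -> list[ContrastRow]:
    """Model suite for every variable × extreme on one working tree."""
    by_id = {s.species_id: s for s in summaries}
    td = pg.TreeData(tree)
    states = [by_id[l].state for l in td.labels]
    X = pg.build_design(states)
    rows = []
    for var in config.variables:
        for extreme in config.extremes:
            y = np.array(
                [
                    by_id[l].limits[var].trimmed_min
                    if extreme == "min"
                    else by_id[l].limits[var].trimmed_max
                    for l in td.labels
                ]
            )
            sel = pg.model_suite(y, X, td, config.method, config.alpha)
            fit = sel.best
            rows.append(
                ContrastRow(
                    clade=clade_label,
                    variable=var,
                    extreme=extreme,
                    schemes=str(SCHEME_NUMBER[scheme]),
                    best_model=FAMILY_DISPLAY[fit.model.family],
                    theta=fit.model.theta,
                    mean_c3=fit.mean_c3,
                    mean_c4=fit.mean_c4,
                    difference=fit.beta1,
                    p=fit.p_value,
                    significant=fit.p_value <= config.alpha,
                    agreement=sel.agreement,
                )
            )
    return rows


def merge_scheme_rows(rows: list[ContrastRow]) -> list[ContrastRow]:
    """Merge rows across schemes that agree on best model, significance and sign.

    The merged row carries the numbers of the first (lowest-numbered) scheme
    in the merged set and a combined scheme label like ``"1, 2, 3"``.
    """
    out: list[ContrastRow] = []
    groups: dict[tuple, list[ContrastRow]] = {}
    order: list[tuple] = []
    for r in rows:
        key = (r.clade, r.variable, r.extreme)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)
    for key in order:
        group = sorted(groups[key], key=lambda r: int(r.schemes))
        buckets: dict[tuple, list[ContrastRow]] = {}
        bucket_order: list[tuple] = []
        for r in group:
            bkey = (r.best_model, r.significant, np.sign(r.difference))
            if bkey not in buckets:
                buckets[bkey] = []
                bucket_order.append(bkey)
            buckets[bkey].append(r)
        for bkey in bucket_order:
            members = buckets[bkey]
            first = members[0]
            merged = ContrastRow(**{**first.__dict__})
            merged.schemes = ", ".join(r.schemes for r in members)
            merged.agreement = all(r.agreement for r in members)
            out.append(merged)
    return out


def run_contrasts(config: RunConfig, merge: bool = True) -> list[ContrastRow]:
    """The full analysis: one merged row per clade × variable × extreme (× scheme)."""
    summaries = compute_summaries(config)
    if not summaries:
        raise ReconciliationError("no species survived the record-count filter")
    trees = build_working_trees(config)
    rows: list[ContrastRow] = []
    scopes = config.clades if config.clades else [WHOLE_TREE]
    for scheme, tree in trees.items():
        tree = _reconcile(tree, summaries)
        for scope in scopes:
            scope_tree = tree if scope == WHOLE_TREE else bt.extract_clade(tree, scope)
            scope_leaves = set(bt.leaf_labels(scope_tree))
            scope_summaries = [s for s in summaries if s.species_id in scope_leaves]
            rows.extend(fit_contrasts(scope_summaries, scope_tree, config, scope, scheme))
    # stable order: clade, variable, extreme, scheme
    scope_rank = {s: i for i, s in enumerate(scopes)}
    var_rank = {v: i for i, v in enumerate(config.variables)}
    ext_rank = {e: i for i, e in enumerate(config.extremes)}
    rows.sort(
        key=lambda r: (scope_rank[r.clade], var_rank[r.variable],
                       ext_rank[r.extreme], int(r.schemes))
    )
    return merge_scheme_rows(rows) if merge else rows


REPORT_COLUMNS = [
    "clade", "variable", "extreme", "schemes", "best_model", "theta",
    "mean_C3", "mean_C4", "difference", "p", "significant", "agreement",
]

FOOTER = (
    "# p-values are per-row (no multiple-testing correction), matching the "
    "classic contrast-table convention."
)


def rows_to_frame(rows: list[ContrastRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "clade": r.clade,
                "variable": r.variable,
                "extreme": r.extreme,
                "schemes": r.schemes,
                "best_model": r.best_model,
                "theta": np.nan if r.theta is None else round(r.theta, 4),
                "mean_C3": round(r.mean_c3, 4),
                "mean_C4": round(r.mean_c4, 4),
                "difference": round(r.difference, 4),
                "p": round(r.p, 4),
                "significant": r.significant,
                "agreement": r.agreement,
            }
            for r in rows
        ],
        columns=REPORT_COLUMNS,
    )


def write_report(rows: list[ContrastRow], destination: str | IO[str],
                 summary_destination: str | None = None) -> None:
    """Write the TSV report (and optionally a human-readable summary)."""
    if not rows:
        raise ValueError("no rows to report")
    df = rows_to_frame(rows)
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    text = buf.getvalue()
    if isinstance(destination, str):
        Path(destination).write_text(text, encoding="utf-8")
    else:
        destination.write(text)
    if summary_destination:
        lines = ["C3/C4 niche-limit contrasts", "=" * 30, ""]
        for r in rows:
            star = "*" if r.significant else " "
            lines.append(
                f"{star} {r.clade:>12} {r.variable:>5} {r.extreme:>3} "
                f"(schemes {r.schemes}): best {r.best_model:<9} "
                f"C3={r.mean_c3:8.4f} C4={r.mean_c4:8.4f} "
                f"diff={r.difference:+8.4f} p={r.p:.4f}"
                + ("" if r.agreement else "  [ΔAIC≤10 models disagree]")
            )
        lines += ["", FOOTER]
        Path(summary_destination).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_report(source: str | IO[str]) -> pd.DataFrame:
    """Read a written TSV report back (round-trip partner of write_report)."""
    return pd.read_csv(source, sep="\t")
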