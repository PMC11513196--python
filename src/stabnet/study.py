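"""End-to-end orchestration of the six-network study design.

A study runs, from one config and one seed: transform fitting on the training
split, application to both splits, network estimation per recipe, node
measures (training and hold-out predictability, centralities, spanning tree),
optional stability diagnostics, and train/test similarity per recipe.

The default roster mirrors the six-model design of an ERP
individual-differences study: each ERP amplitude node with and without
covariates, and the two amplitude nodes together with and without covariates.
Covariate recipes include the latency node matching each included amplitude
(both latencies in the combined models).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import DataTable
from .measures import all_measures, maximal_spanning_tree
from .model import AdaptiveGGM, PenaltyScheme, _jsonable
from .stability import compare_networks, edge_bootstrap, measure_stability
from .transforms import TransformPipeline

logger = logging.getLogger(__name__)


@dataclass
class Recipe:
    """One network model: which ERP amplitude nodes, with covariates or not."""

    name: str
    amplitude_nodes: list[str]
    with_covariates: bool = False
    spanning_tree: bool = False


@dataclass
class StudyConfig:
    """Full study configuration; one seed governs the entire run."""

    train_table: str | None = None
    test_table: str | None = None
    epochs_dir: str | None = None
    recipes: list[Recipe] | None = None
    B: int = 1000
    tau: float = 0.65
    scheme: PenaltyScheme = field(default_factory=PenaltyScheme)
    skew_limit: float = 2.0
    erp_window: tuple[float, float] = (0.0, 100.0)
    min_trials: int = 5
    min_dependability: float = 0.70
    stability_bootstrap_B: int = 0  # 0 = skip the bootstrap stage
    stability_inner_B: int = 100
    stability_measures: list[str] = field(default_factory=list)
    seed: int = 0
    output_dir: str = "study_output"

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "scheme" in payload and isinstance(payload["scheme"], dict):
            payload["scheme"] = PenaltyScheme(**payload["scheme"])
        if "recipes" in payload and payload["recipes"] is not None:
            payload["recipes"] = [Recipe(**r) for r in payload["recipes"]]
        if "erp_window" in payload:
            payload["erp_window"] = tuple(payload["erp_window"])
        return cls(**payload)


def default_recipes(table: DataTable) -> list[Recipe]:
    """The six-model roster built from the table's ERP amplitude nodes."""
    amps = table.columns_with_role("erp_amplitude")
    if len(amps) < 2:
        raise ValueError(
            f"default roster needs two ERP amplitude nodes, found {amps}"
        )
    a1, a2 = amps[:2]
    return [
        Recipe(f"{a1.lower()}", [a1]),
        Recipe(f"{a1.lower()}_covariates", [a1], with_covariates=True),
        Recipe(f"{a2.lower()}", [a2]),
        Recipe(f"{a2.lower()}_covariates", [a2], with_covariates=True),
        Recipe(f"{a1.lower()}_{a2.lower()}", [a1, a2]),
        Recipe(
            f"{a1.lower()}_{a2.lower()}_covariates",
            [a1, a2],
            with_covariates=True,
            spanning_tree=True,
        ),
    ]


def _latency_for(table: DataTable, amplitude: str) -> list[str]:
    lat = table.columns_with_role("erp_latency")
    return [c for c in lat if c.lower().startswith(amplitude.lower())]


def recipe_columns(table: DataTable, recipe: Recipe) -> list[str]:
    cols = table.columns_with_role("trait") + [
        a for a in recipe.amplitude_nodes if a in table.columns
    ]
    missing = [a for a in recipe.amplitude_nodes if a not in table.columns]
    if missing:
        raise ValueError(f"recipe {recipe.name!r}: variables not in table: {missing}")
    if recipe.with_covariates:
        cols += table.columns_with_role("covariate")
        for a in recipe.amplitude_nodes:
            cols += _latency_for(table, a)
    return cols


# ---------------------------------------------------------------------------
# edge list <-> matrix helpers (round-trip safe for symmetric matrices)
# ---------------------------------------------------------------------------
def matrix_to_edges(M: np.ndarray, labels: list[str]) -> pd.DataFrame:
    iu = np.triu_indices(len(labels), k=1)
    return pd.DataFrame(
        {
            "node_i": [labels[i] for i in iu[0]],
            "node_j": [labels[j] for j in iu[1]],
            "weight": M[iu],
        }
    )


def edges_to_matrix(edges: pd.DataFrame, labels: list[str]) -> np.ndarray:
    pos = {lab: k for k, lab in enumerate(labels)}
    M = np.zeros((len(labels), len(labels)))
    for _, row in edges.iterrows():
        i, j = pos[row["node_i"]], pos[row["node_j"]]
        M[i, j] = M[j, i] = row["weight"]
    return M


# ---------------------------------------------------------------------------
# study runner
# ---------------------------------------------------------------------------
def run_study(
    config: StudyConfig,
    train: DataTable | None = None,
    test: DataTable | None = None,
) -> dict:
    """Execute the full roster; returns the in-memory report bundle.

    Tables may be passed directly (e.g. fresh from the synthetic generator) or
    read from the paths in the config.  Failures are structured per
    recipe/stage; prior recipes' outputs are retained on disk.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_study(config, train, test, out_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_study(config, train, test, out_dir: Path) -> dict:
    if train is None:
        if config.train_table is None:
            raise ValueError("no training table (path or object) provided")
        train = DataTable.read(config.train_table)
    if test is None and config.test_table is not None:
        test = DataTable.read(config.test_table)
    if test is None:
        logger.info("no test table: hold-out and similarity stages will be skipped")

    pipe = TransformPipeline(skew_limit=config.skew_limit)
    train_t = pipe.fit_transform(train)
    pipe.to_json(out_dir / "transform.json")
    if pipe.dropped:
        logger.info("normality screen dropped: %s", pipe.dropped)
    test_t = pipe.transform(test) if test is not None else None

    recipes = config.recipes or default_recipes(train_t)
    seeds = np.random.SeedSequence(config.seed).spawn(len(recipes))
    report: dict = {"recipes": {}, "config": _jsonable(dataclasses.asdict(config))}
    for recipe, ss in zip(recipes, seeds):
        rdir = out_dir / recipe.name
        try:
            report["recipes"][recipe.name] = _run_recipe(
                config, recipe, train_t, test_t, rdir,
                seed=int(ss.generate_state(1)[0] % (2**31 - 1)),
            )
        except Exception as exc:  # keep earlier outputs, surface the stage
            logger.exception("recipe %s failed", recipe.name)
            raise RuntimeError(f"recipe {recipe.name!r} failed: {exc}") from exc
    n_models = len(report["recipes"])
    report["n_models"] = n_models
    (out_dir / "report.json").write_text(json.dumps(_jsonable(report), indent=1))
    logger.info("study complete: %d models", n_models)
    return report


def _run_recipe(
    config: StudyConfig,
    recipe: Recipe,
    train_t: DataTable,
    test_t: DataTable | None,
    rdir: Path,
    seed: int,
) -> dict:
    cols = recipe_columns(train_t, recipe)
    tr = train_t.select(cols)
    model = AdaptiveGGM(
        tr, B=config.B, tau=config.tau, scheme=config.scheme, seed=seed
    )
    res = model.fit()
    res.save(rdir)
    logger.info("recipe %s: %d nodes, %d edges", recipe.name, res.p, res.n_edges)

    te = test_t.select(cols) if test_t is not None else None
    meas = all_measures(res, te)
    meas.to_csv(rdir / "measures.csv", index=False)

    entry: dict = {
        "n_nodes": res.p,
        "n_edges": res.n_edges,
        "seed": seed,
        "columns": cols,
    }
    if recipe.spanning_tree:
        tree = maximal_spanning_tree(res)
        tree.to_frame().to_csv(rdir / "spanning_tree.tsv", sep="\t", index=False)
        entry["spanning_tree_weight"] = tree.total_weight

    if te is not None:
        test_model = AdaptiveGGM(
            te, B=config.B, tau=config.tau, scheme=config.scheme, seed=seed
        )
        test_res = test_model.fit()
        test_res.save(rdir / "test_network")
        sim = compare_networks(res, test_res, scope="full")
        entry["similarity"] = dataclasses.asdict(sim)
        entry["row_similarity"] = {}
        for a in recipe.amplitude_nodes:
            rs = compare_networks(res, test_res, scope="row", node=a)
            entry["row_similarity"][a] = dataclasses.asdict(rs)

    if config.stability_bootstrap_B > 0:
        boot = edge_bootstrap(
            tr,
            config={"B": config.stability_inner_B, "tau": config.tau,
                    "scheme": config.scheme},
            B=config.stability_bootstrap_B,
            seed=seed,
            reference=res,
        )
        boot.stability_table().to_csv(rdir / "edge_stability.csv", index=False)
        entry["edge_bootstrap_B"] = boot.B
    for measure in config.stability_measures:
        curve = measure_stability(
            tr,
            config={"B": config.stability_inner_B, "tau": config.tau,
                    "scheme": config.scheme},
            measure=measure,
            seed=seed,
            reference=res,
        )
        curve.to_frame().to_csv(rdir / f"stability_{measure}.csv", index=False)
        entry.setdefault("cs_coefficients", {})[measure] = curve.cs_coefficient

    (rdir / "recipe.json").write_text(json.dumps(_jsonable(entry), indent=1))
    return entry
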