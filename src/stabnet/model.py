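"""Adaptive random-Lasso Gaussian graphical model with stability selection.

The estimator follows a three-step adaptive procedure:

1. *Initial support.*  An ensemble of ``B`` graphical-Lasso fits, each on a
   bootstrap resample of the rows with a randomly drawn penalty, votes on
   which precision entries are nonzero; the per-edge vote frequencies form a
   proportion matrix.
2. *Thresholding.*  Edges whose nonzero frequency strictly exceeds ``tau``
   (default 65%) enter the binary support.
3. *Refit.*  A support-constrained Gaussian maximum-likelihood fit (penalty 0
   on supported entries, prohibitively large elsewhere) yields the final
   precision matrix and its partial-correlation network.

The public surface is the :class:`AdaptiveGGM` model object, whose ``fit``
returns a :class:`GGMResults`; the module-level functions expose the
individual stages for direct use and testing.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DataTable
from .glasso import (
    ConvergenceError,
    empirical_covariance,
    graphical_lasso,
)

NONZERO_TOL = 1e-8  # |theta_ij| above this counts as a present edge
BIG_PENALTY_FACTOR = 1e6  # off-support penalty multiplier in the refit


# ---------------------------------------------------------------------------
# penalty scheme
# ---------------------------------------------------------------------------
@dataclass
class PenaltyScheme:
    """Random-penalty generator for the stability-selection ensemble.

    ``scalar-random`` draws one log-uniform lambda and broadcasts it to all
    off-diagonal entries; ``entrywise-random`` additionally multiplies each
    off-diagonal entry by an independent uniform factor in
    ``[perturbation_floor, 1]``, symmetrized.

    With ``scale='absolute'`` (default) lambda is log-uniform on
    ``[lambda_low, lambda_high]``, an interval on the correlation scale of
    standardized data: the default [0.05, 0.5] spans from just above sampling
    noise at a few hundred subjects up to the largest association worth
    killing.  An absolute scale is what lets the ensemble return an empty
    network on pure-noise data, where any data-relative range would chase the
    noise.  ``scale='relative'`` instead uses
    ``[lambda_min_ratio * lambda_max, lambda_max]`` with lambda_max the
    largest off-diagonal |S| of each resample.
    """

    kind: str = "scalar-random"
    scale: str = "absolute"
    lambda_low: float = 0.05
    lambda_high: float = 0.5
    lambda_min_ratio: float = 0.01
    perturbation_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("scalar-random", "entrywise-random"):
            raise ValueError(f"unknown penalty scheme kind {self.kind!r}")
        if self.scale not in ("absolute", "relative"):
            raise ValueError("scale must be 'absolute' or 'relative'")
        if not 0 < self.lambda_low <= self.lambda_high:
            raise ValueError("need 0 < lambda_low <= lambda_high")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if not 0 < self.perturbation_floor <= 1:
            raise ValueError("perturbation_floor must be in (0, 1]")


def draw_penalty(S: np.ndarray, scheme: PenaltyScheme, rng: np.random.Generator) -> np.ndarray:
    """Draw one random penalty matrix for covariance ``S`` under ``scheme``."""
    p = S.shape[0]
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max())
    if lam_max <= 0:
        raise ValueError("S has no off-diagonal signal (lambda_max = 0)")
    if scheme.scale == "relative":
        lo, hi = np.log(scheme.lambda_min_ratio * lam_max), np.log(lam_max)
    else:
        lo, hi = np.log(scheme.lambda_low), np.log(scheme.lambda_high)
    lam = float(np.exp(rng.uniform(lo, hi)))
    P = np.full((p, p), lam)
    if scheme.kind == "entrywise-random":
        F = rng.uniform(scheme.perturbation_floor, 1.0, size=(p, p))
        F = 0.5 * (F + F.T)
        P = P * F
    np.fill_diagonal(P, 0.0)
    return P


# ---------------------------------------------------------------------------
# proportion matrix
# ---------------------------------------------------------------------------
@dataclass
class ProportionMatrix:
    """Per-edge nonzero frequencies across the stability-selection ensemble."""

    node_labels: list[str]
    proportions: np.ndarray
    B: int

    def __post_init__(self) -> None:
        P = np.asarray(self.proportions, dtype=float)
        if not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("proportions must be symmetric")
        if P.min() < 0 or P.max() > 1:
            raise ValueError("proportions must lie in [0, 1]")
        np.fill_diagonal(P, 1.0)
        self.proportions = P

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.node_labels, columns=self.node_labels)


def threshold_support(proportions: ProportionMatrix | np.ndarray, tau: float = 0.65) -> np.ndarray:
    """Binary support: 1 where the nonzero frequency strictly exceeds ``tau``."""
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    P = proportions.proportions if isinstance(proportions, ProportionMatrix) else np.asarray(proportions)
    support = (P > tau).astype(int)
    np.fill_diagonal(support, 0)
    return support


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------
def stability_ensemble(
    table: DataTable | np.ndarray,
    B: int = 1000,
    scheme: PenaltyScheme | None = None,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 2000,
    node_labels: list[str] | None = None,
) -> ProportionMatrix:
    """Vote on edge presence over ``B`` bootstrapped, randomly penalized fits.

    Each iteration resamples the n rows with replacement (full size), forms the
    ML covariance, draws a penalty from ``scheme`` and runs the graphical
    Lasso; entries with |theta| > 1e-8 count as nonzero.  Iterations whose fit
    fails are dropped (and counted); more than 10% failures is an error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    scheme = scheme or PenaltyScheme()
    if isinstance(table, DataTable):
        X = table.values()
        node_labels = node_labels or table.columns
    else:
        X = np.asarray(table, dtype=float)
        node_labels = node_labels or [f"v{i:02d}" for i in range(X.shape[1])]
    n, p = X.shape
    rng = np.random.default_rng(seed)
    counts = np.zeros((p, p))
    n_ok = 0
    n_fail = 0
    for _b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            S = empirical_covariance(X[idx])
            P = draw_penalty(S, scheme, rng)
            theta = graphical_lasso(S, P, tol=tol, max_iter=max_iter)
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            n_fail += 1
            continue
        counts += (np.abs(theta) > NONZERO_TOL).astype(float)
        n_ok += 1
    if n_fail > 0.10 * B:
        raise RuntimeError(f"{n_fail}/{B} ensemble members failed (> 10%)")
    props = counts / max(n_ok, 1)
    np.fill_diagonal(props, 1.0)
    return ProportionMatrix(node_labels=node_labels, proportions=props, B=n_ok)


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------
@dataclass
class GGMResults:
    """Estimated partial-correlation network.

    Attributes
    ----------
    node_labels : list of str
    theta : (p, p) estimated precision matrix (symmetric PD).
    partial_corr : (p, p) partial correlations, unit diagonal.
    support : (p, p) binary symmetric edge indicator.
    proportions : ProportionMatrix or None
        Stability-selection vote frequencies, when the full procedure ran.
    config : dict — estimation settings (B, tau, penalty scheme, seed).
    provenance : dict — input hash and UTC timestamp.
    """

    node_labels: list[str]
    theta: np.ndarray
    support: np.ndarray
    config: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    proportions: ProportionMatrix | None = None
    partial_corr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        th = 0.5 * (self.theta + self.theta.T)
        d = np.sqrt(np.diag(th))
        pc = -th / np.outer(d, d)
        np.fill_diagonal(pc, 1.0)
        self.theta = th
        self.partial_corr = pc
        self.support = np.asarray(self.support, dtype=int)

    @property
    def p(self) -> int:
        return self.theta.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.support.sum() // 2)

    def edge_list(self) -> pd.DataFrame:
        """Tidy edge list over all node pairs (upper triangle)."""
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                rows.append(
                    {
                        "node_i": self.node_labels[i],
                        "node_j": self.node_labels[j],
                        "weight": self.partial_corr[i, j],
                        "support": int(self.support[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def to_graph(self):
        """Weighted undirected graph over supported edges (networkx)."""
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.node_labels)
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.support[i, j]:
                    w = float(self.partial_corr[i, j])
                    G.add_edge(
                        self.node_labels[i], self.node_labels[j],
                        weight=w, abs_weight=abs(w),
                    )
        return G

    # measures are implemented in .measures and surfaced here for convenience
    def predictability(self):
        from .measures import predictability

        return predictability(self)

    def holdout_predictability(self, test: DataTable):
        from .measures import holdout_predictability

        return holdout_predictability(self, test)

    def degree_centrality(self):
        from .measures import degree_centrality

        return degree_centrality(self)

    def current_flow_closeness(self):
        from .measures import current_flow_closeness

        return current_flow_closeness(self)

    def classical_centralities(self):
        from .measures import classical_centralities

        return classical_centralities(self)

    def spanning_tree(self):
        from .measures import maximal_spanning_tree

        return maximal_spanning_tree(self)

    def summary(self) -> str:
        """Human-readable estimation summary."""
        lines = [
            "Adaptive stability-selected GGM",
            "=" * 47,
            f"nodes: {self.p}   edges: {self.n_edges} "
            f"of {self.p * (self.p - 1) // 2} possible",
        ]
        cfg = self.config
        if cfg:
            lines.append(
                f"ensemble B={cfg.get('B')}  tau={cfg.get('tau')}  "
                f"scheme={cfg.get('scheme', {}).get('kind')}  seed={cfg.get('seed')}"
            )
        pr = self.predictability()
        lines.append("")
        lines.append(f"{'node':<16}{'degree':>8}{'R2 %':>9}  strongest edge")
        deg = self.degree_centrality()
        for i, lab in enumerate(self.node_labels):
            row = np.abs(self.partial_corr[i] * self.support[i])
            j = int(np.argmax(row))
            partner = (
                f"{self.node_labels[j]} ({self.partial_corr[i, j]:+.2f})"
                if row[j] > 0
                else "-"
            )
            lines.append(f"{lab:<16}{deg[i]:>8.2f}{pr[i]:>9.2f}  {partner}")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write precision/partial-correlation CSVs, edge list TSV, GraphML, JSON."""
        import networkx as nx

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        idx = self.node_labels
        pd.DataFrame(self.theta, index=idx, columns=idx).to_csv(directory / "precision.csv")
        pd.DataFrame(self.partial_corr, index=idx, columns=idx).to_csv(
            directory / "partial_correlation.csv"
        )
        self.edge_list().to_csv(directory / "edges.tsv", sep="\t", index=False)
        nx.write_graphml(self.to_graph(), directory / "network.graphml")
        meta = {"config": _jsonable(self.config), "provenance": self.provenance}
        (directory / "estimation.json").write_text(json.dumps(meta, indent=1))
        if self.proportions is not None:
            self.proportions.to_frame().to_csv(directory / "proportions.csv")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, PenaltyScheme):
        return asdict(obj)
    return obj


# ---------------------------------------------------------------------------
# refit
# ---------------------------------------------------------------------------
def refit_support(
    table: DataTable | np.ndarray,
    support: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 10000,
    node_labels: list[str] | None = None,
    config: dict | None = None,
    proportions: ProportionMatrix | None = None,
) -> GGMResults:
    """Support-constrained Gaussian ML fit of the precision matrix.

    Realized as a graphical Lasso with zero penalty on supported entries and a
    prohibitively large penalty (1e6 x lambda_max) elsewhere, which drives
    off-support entries below 1e-8 in magnitude.
    """
    if isinstance(table, DataTable):
        X = table.values()
        node_labels = node_labels or table.columns
    else:
        X = np.asarray(table, dtype=float)
        node_labels = node_labels or [f"v{i:02d}" for i in range(X.shape[1])]
    support = np.asarray(support)
    if not np.array_equal(support, support.T):
        raise ValueError("support must be symmetric")
    support = (support != 0).astype(int)
    np.fill_diagonal(support, 0)

    S = empirical_covariance(X)
    p = S.shape[0]
    provenance = {
        "input_sha256": hashlib.sha256(np.ascontiguousarray(X).tobytes()).hexdigest(),
        "n": int(X.shape[0]),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if support.sum() == 0:
        warnings.warn("empty support: returning a diagonal (edge-free) model")
        theta = np.diag(1.0 / np.diag(S))
        return GGMResults(node_labels, theta, support, config or {}, provenance, proportions)

    off = np.abs(S - np.diag(np.diag(S)))
    big = BIG_PENALTY_FACTOR * max(off.max(), 1.0)
    P = np.where(support == 1, 0.0, big)
    np.fill_diagonal(P, 0.0)
    theta = graphical_lasso(S, P, tol=tol, max_iter=max_iter)
    theta[(support == 0) & ~np.eye(p, dtype=bool)] = 0.0  # clean numerical dust
    return GGMResults(node_labels, theta, support, config or {}, provenance, proportions)


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------
class AdaptiveGGM:
    """Adaptive random-Lasso GGM estimator over a standardized data table.

    Parameters
    ----------
    table : DataTable or (n, p) array
        Subjects x variables data; expected transformed and standardized.
    B : int
        Ensemble size for stability selection (study default 1000).
    tau : float
        Edge-frequency threshold; strict exceedance (study default 0.65).
    scheme : PenaltyScheme
        Random-penalty distribution for the ensemble.
    seed : int
        Governs the bootstrap resamples and penalty draws.

    Examples
    --------
    >>> model = AdaptiveGGM(table, B=200, seed=7)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        table: DataTable | np.ndarray,
        B: int = 1000,
        tau: float = 0.65,
        scheme: PenaltyScheme | None = None,
        seed: int = 0,
        ensemble_tol: float = 1e-5,
        refit_tol: float = 1e-7,
    ):
        self.table = table
        self.B = int(B)
        self.tau = float(tau)
        self.scheme = scheme or PenaltyScheme()
        self.seed = int(seed)
        self.ensemble_tol = ensemble_tol
        self.refit_tol = refit_tol

    def config(self) -> dict:
        return {
            "B": self.B,
            "tau": self.tau,
            "scheme": asdict(self.scheme),
            "seed": self.seed,
        }

    def fit(self) -> GGMResults:
        """Run stability selection, threshold the votes, refit on the support."""
        props = stability_ensemble(
            self.table, B=self.B, scheme=self.scheme, seed=self.seed,
            tol=self.ensemble_tol,
        )
        support = threshold_support(props, self.tau)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty-support warning ok here
            res = refit_support(
                self.table, support,
                tol=self.refit_tol,
                config=self.config(),
                proportions=props,
            )
        return res


def estimate_network(
    table: DataTable | np.ndarray, config: dict | None = None
) -> tuple[GGMResults, ProportionMatrix]:
    """Functional wrapper over :class:`AdaptiveGGM` (three-step procedure)."""
    cfg = dict(config or {})
    scheme_cfg = cfg.pop("scheme", None)
    scheme = PenaltyScheme(**scheme_cfg) if isinstance(scheme_cfg, dict) else scheme_cfg
    model = AdaptiveGGM(table, scheme=scheme, **cfg)
    res = model.fit()
    return res, res.proportions
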