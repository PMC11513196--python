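"""Stability and replication diagnostics for estimated networks.

Covers: bootstrapped edge-weight confidence intervals with per-edge
sensitivity/specificity, paired bootstrap difference tests for edges and
centralities, train/test network similarity (Pearson r and Hamming), and
case-dropping measure-stability curves with the CS coefficient.

All bootstrap machinery re-runs the full adaptive estimation procedure with a
configurable reduced inner ensemble, so the diagnostics reflect the actual
estimator rather than a cheaper surrogate.  Difference tests require *paired*
bootstraps: the same resample indices (same seed, sample size and replicate
count) driving both models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DataTable
from .model import AdaptiveGGM, GGMResults, PenaltyScheme
from . import measures as _measures


def _fit_once(X: np.ndarray, labels: list[str], config: dict, seed: int) -> GGMResults:
    cfg = dict(config)
    scheme = cfg.pop("scheme", None)
    if isinstance(scheme, dict):
        scheme = PenaltyScheme(**scheme)
    cfg.pop("seed", None)
    df = pd.DataFrame(X, columns=labels)
    model = AdaptiveGGM(df.to_numpy(), scheme=scheme, seed=seed, **cfg)
    res = model.fit()
    res.node_labels = labels
    return res


# ---------------------------------------------------------------------------
# edge bootstrap
# ---------------------------------------------------------------------------
@dataclass
class EdgeBootstrap:
    """Per-resample edge weights/presence from re-running the estimator.

    ``weights`` and ``present`` are (B, p, p) arrays of partial correlations
    and support indicators; ``pairing`` identifies the resample stream so two
    bootstraps can be checked for pairedness before a difference test.
    """

    node_labels: list[str]
    weights: np.ndarray
    present: np.ndarray
    thetas: np.ndarray
    reference: GGMResults
    pairing: tuple  # (seed, n, B)

    @property
    def B(self) -> int:
        return self.weights.shape[0]

    def edge_index(self, a: str, b: str) -> tuple[int, int]:
        i = self.node_labels.index(a)
        j = self.node_labels.index(b)
        return (i, j) if i < j else (j, i)

    def edge_distribution(self, a: str, b: str) -> np.ndarray:
        i, j = self.edge_index(a, b)
        return self.weights[:, i, j]

    def stability_table(self) -> pd.DataFrame:
        """Per-edge mean weight, percentile 95% CI, sensitivity/specificity.

        Sensitivity (fraction of bootstraps where the edge appears) is defined
        for edges present in the reference network; specificity (fraction
        where it stays absent) for edges absent from it.
        """
        p = len(self.node_labels)
        rows = []
        for i in range(p):
            for j in range(i + 1, p):
                w = self.weights[:, i, j]
                pres = self.present[:, i, j]
                in_ref = bool(self.reference.support[i, j])
                rows.append(
                    {
                        "node_i": self.node_labels[i],
                        "node_j": self.node_labels[j],
                        "reference_weight": self.reference.partial_corr[i, j]
                        * self.reference.support[i, j],
                        "in_reference": in_ref,
                        "mean_weight": float(w.mean()),
                        "ci_low": float(np.percentile(w, 2.5)),
                        "ci_high": float(np.percentile(w, 97.5)),
                        "sensitivity": float(pres.mean()) if in_ref else np.nan,
                        "specificity": float(1.0 - pres.mean()) if not in_ref else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def measure_distribution(self, measure: str) -> np.ndarray:
        """(B, p) per-resample node values of a named measure."""
        func = _measures.MEASURE_FUNCS[measure]
        out = np.empty((self.B, len(self.node_labels)))
        for b in range(self.B):
            res = GGMResults(
                node_labels=self.node_labels,
                theta=self.thetas[b],
                support=self.present[b],
            )
            out[b] = func(res)
        return out


def edge_bootstrap(
    table: DataTable,
    config: dict | None = None,
    B: int = 1000,
    seed: int = 0,
    reference: GGMResults | None = None,
) -> EdgeBootstrap:
    """Bootstrap the full adaptive estimator to get edge-weight distributions.

    ``config`` holds :class:`AdaptiveGGM` keyword arguments; its ``B`` entry is
    the *inner* ensemble size (default 100, reduced from the reference 1000
    for tractability inside the bootstrap).
    """
    if B < 100:
        warnings.warn("B < 100 bootstrap resamples: percentile CIs will be unstable")
    cfg = {"B": 100, "tau": 0.65}
    cfg.update(config or {})
    labels = table.columns if isinstance(table, DataTable) else [
        f"v{i:02d}" for i in range(np.asarray(table).shape[1])
    ]
    X = table.values() if isinstance(table, DataTable) else np.asarray(table, float)
    n, p = X.shape
    if reference is None:
        reference = _fit_once(X, labels, cfg, seed=seed)
    rng = np.random.default_rng(seed)
    weights = np.empty((B, p, p))
    present = np.empty((B, p, p), dtype=np.int8)
    thetas = np.empty((B, p, p))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = _fit_once(X[idx], labels, cfg, seed=sub_seed)
        weights[b] = res.partial_corr * res.support
        present[b] = res.support
        thetas[b] = res.theta
    return EdgeBootstrap(
        node_labels=labels,
        weights=weights,
        present=present,
        thetas=thetas,
        reference=reference,
        pairing=(seed, n, B),
    )


# ---------------------------------------------------------------------------
# paired difference tests
# ---------------------------------------------------------------------------
def _check_paired(a: EdgeBootstrap, b: EdgeBootstrap) -> None:
    if a.pairing != b.pairing:
        raise ValueError(
            f"bootstraps are not paired (seed, n, B): {a.pairing} vs {b.pairing}; "
            "difference tests need identical resample indices"
        )


def paired_bootstrap_p(diff: np.ndarray) -> float:
    """Two-sided bootstrap p from paired differences, floored at 1/B."""
    diff = np.asarray(diff, dtype=float)
    B = len(diff)
    p = 2.0 * min(float(np.mean(diff <= 0)), float(np.mean(diff >= 0)))
    return float(min(1.0, max(p, 1.0 / B)))


def edge_difference_test(
    boot_a: EdgeBootstrap, boot_b: EdgeBootstrap, edge: tuple[str, str]
) -> float:
    """Paired bootstrap test that one edge's weight differs between models."""
    _check_paired(boot_a, boot_b)
    da = boot_a.edge_distribution(*edge)
    db = boot_b.edge_distribution(*edge)
    return paired_bootstrap_p(da - db)


def centrality_difference_test(
    boot_a: EdgeBootstrap,
    boot_b: EdgeBootstrap,
    node: str,
    measure: str = "degree",
) -> float:
    """Paired bootstrap test on a node's centrality difference between models."""
    _check_paired(boot_a, boot_b)
    ia = boot_a.node_labels.index(node)
    ib = boot_b.node_labels.index(node)
    da = boot_a.measure_distribution(measure)[:, ia]
    db = boot_b.measure_distribution(measure)[:, ib]
    return paired_bootstrap_p(da - db)


# ---------------------------------------------------------------------------
# network similarity
# ---------------------------------------------------------------------------
@dataclass
class SimilarityReport:
    pearson_r: float
    pearson_p: float
    hamming_similarity: float  # 1 - mismatches / compared entries
    scope: str = "full-network"
    n_compared: int = 0


def compare_networks(
    model_a: GGMResults,
    model_b: GGMResults,
    scope: str = "full",
    node: str | None = None,
) -> SimilarityReport:
    """Similarity of two networks on the same node set.

    ``full`` compares the vectorized upper-triangle weighted adjacencies
    (Pearson r with p-value) and the binarized supports (Hamming similarity);
    ``row`` restricts to one node's incident edges — the one-dimensional
    association structure of, e.g., an ERP amplitude node.  Pearson r on
    near-binary vectors is reported but should be read with caution.
    """
    if list(model_a.node_labels) != list(model_b.node_labels):
        raise ValueError("node label sets differ; cannot compare networks")
    wa = model_a.partial_corr * model_a.support
    wb = model_b.partial_corr * model_b.support
    if scope == "full":
        iu = np.triu_indices(model_a.p, k=1)
        va, vb = wa[iu], wb[iu]
        sa, sb = model_a.support[iu], model_b.support[iu]
    elif scope == "row":
        if node is None:
            raise ValueError("row scope needs a node")
        i = model_a.node_labels.index(node)
        keep = np.arange(model_a.p) != i
        va, vb = wa[i, keep], wb[i, keep]
        sa, sb = model_a.support[i, keep], model_b.support[i, keep]
    else:
        raise ValueError("scope must be 'full' or 'row'")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        r, pval = (1.0, 0.0) if np.allclose(va, vb) else (np.nan, np.nan)
    else:
        r, pval = stats.pearsonr(va, vb)
    ham = 1.0 - float(np.mean(sa != sb))
    return SimilarityReport(
        pearson_r=float(r),
        pearson_p=float(pval),
        hamming_similarity=ham,
        scope="full-network" if scope == "full" else f"row({node})",
        n_compared=len(va),
    )


# ---------------------------------------------------------------------------
# case-dropping measure stability
# ---------------------------------------------------------------------------
@dataclass
class StabilityCurve:
    measure: str
    fractions: list[float]  # retained fractions, strictly decreasing
    mean_correlation: list[float]
    correlations: dict[float, np.ndarray] = field(default_factory=dict)
    cs_coefficient: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fractions:
            for rep, c in enumerate(self.correlations[f]):
                rows.append(
                    {"measure": self.measure, "fraction": f, "rep": rep, "correlation": c}
                )
        return pd.DataFrame(rows)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def measure_stability(
    table: DataTable,
    config: dict | None = None,
    measure: str = "predictability",
    fractions: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3),
    reps: int = 100,
    seed: int = 0,
    reference: GGMResults | None = None,
    cs_threshold: float = 0.7,
    cs_prob: float = 0.95,
) -> StabilityCurve:
    """Case-dropping stability of a node measure.

    For each retained fraction, ``reps`` subsamples are drawn without
    replacement, the network re-estimated (reduced inner ensemble from
    ``config``) and the node measure correlated with its value on the full
    sample.  The CS coefficient is the largest *dropped* proportion for which
    at least ``cs_prob`` of subsamples correlate >= ``cs_threshold`` with the
    original.
    """
    cfg = {"B": 100, "tau": 0.65}
    cfg.update(config or {})
    labels = table.columns
    X = table.values()
    n, p = X.shape
    if reference is None:
        reference = _fit_once(X, labels, cfg, seed=seed)
    ref_vals = _measures.MEASURE_FUNCS[measure](reference)
    rng = np.random.default_rng(seed)
    fracs, means, cors = [], [], {}
    for f in fractions:
        m = int(round(f * n))
        if m < p + 1:
            warnings.warn(f"fraction {f}: subsample {m} < p+1; skipped")
            continue
        cc = np.empty(reps)
        for r in range(reps):
            idx = rng.choice(n, size=m, replace=False)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res = _fit_once(X[idx], labels, cfg, seed=sub_seed)
            cc[r] = _safe_corr(ref_vals, _measures.MEASURE_FUNCS[measure](res))
        fracs.append(f)
        means.append(float(np.nanmean(cc)))
        cors[f] = cc
    cs = 0.0
    for f in fracs:
        cc = cors[f]
        ok = np.mean(np.nan_to_num(cc, nan=-1.0) >= cs_threshold) >= cs_prob
        if ok:
            cs = max(cs, round(1.0 - f, 10))
    return StabilityCurve(
        measure=measure,
        fractions=fracs,
        mean_correlation=means,
        correlations=cors,
        cs_coefficient=cs,
    )
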