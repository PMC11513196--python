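"""Synthetic study generator with known network ground truth.

The generator produces (i) jointly Gaussian subject-level tables whose
population partial-correlation network is known exactly — a sparse precision
matrix built on an Erdős–Rényi-style support — and (ii) trial-level,
response-locked ERP epochs with controllable between/within-subject amplitude
variance and component latency.  Every downstream stage (transforms, network
estimation, measures, stability) can therefore be validated against ground
truth.

Conventions
-----------
* Precision matrices are on the standardized, unit-diagonal scale: the
  population partial correlation between nodes i and j is
  ``-theta[i,j] / sqrt(theta[i,i] * theta[j,j])``.
* Epochs mimic a mediofrontal response-locked component: a Gaussian-shaped
  negative peak (SD 20 ms) on a 256 Hz, -100..600 ms axis, with subject-level
  latent amplitude and latency plus trial noise.
* All generators take explicit integer seeds; no global RNG state is touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DataTable, EpochSet

_MIN_EIG = 0.05  # positive-definiteness floor for generated precisions
_MAX_BOOST = 10.0  # give up if the diagonal boost would exceed this


@dataclass
class PrecisionSpec:
    """Ground-truth precision structure for a synthetic study.

    Attributes
    ----------
    node_labels : list of str
    roles : dict
        Role per node (``trait`` / ``erp_amplitude`` / ``erp_latency`` /
        ``covariate``).
    theta : ndarray
        Symmetric positive-definite precision matrix, unit diagonal.
    true_support : ndarray
        Binary symmetric matrix; 1 exactly where ``theta`` has a nonzero
        off-diagonal entry.
    true_partial_corr : ndarray
        Population partial correlations implied by ``theta`` (unit diagonal).
    """

    node_labels: list[str]
    roles: dict[str, str]
    theta: np.ndarray
    true_support: np.ndarray = field(init=False)
    true_partial_corr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        if th.ndim != 2 or th.shape[0] != th.shape[1]:
            raise ValueError("theta must be square")
        if not np.allclose(th, th.T, atol=1e-12):
            raise ValueError("theta must be symmetric")
        eigmin = float(np.linalg.eigvalsh(th)[0])
        if eigmin <= 0:
            raise ValueError(f"theta must be positive-definite (min eig {eigmin:.3g})")
        d = np.sqrt(np.diag(th))
        pc = -th / np.outer(d, d)
        np.fill_diagonal(pc, 1.0)
        self.theta = th
        self.true_partial_corr = pc
        supp = (np.abs(th) > 1e-12).astype(int)
        np.fill_diagonal(supp, 0)
        self.true_support = supp

    @property
    def p(self) -> int:
        return self.theta.shape[0]

    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.theta)


@dataclass
class EpochSpec:
    """Parameters of the synthetic single-channel epoch generator.

    Amplitudes are in microvolts, times in milliseconds.  ``amp_sd_between``
    spreads the latent subject amplitude; ``amp_sd_within`` jitters it per
    trial; ``noise_sd`` adds white sample noise.
    """

    n_subjects: int = 50
    trials_per_subject: int | list[int] = 28
    sampling_rate: float = 256.0
    epoch_window: tuple[float, float] = (-100.0, 600.0)
    component_window: tuple[float, float] = (0.0, 100.0)
    component_sd: float = 20.0  # ms, width of the Gaussian-shaped peak
    amp_mean: float = -8.0
    amp_sd_between: float = 4.0
    amp_sd_within: float = 8.0
    latency_mean: float = 50.0
    latency_sd: float = 15.0
    noise_sd: float = 1.0
    condition: str = "error"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("amp_sd_between", "amp_sd_within", "latency_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.component_window
        if lo < self.epoch_window[0] or hi > self.epoch_window[1]:
            raise ValueError("component_window must lie inside the epoch window")

    def trial_counts(self) -> np.ndarray:
        t = self.trials_per_subject
        if np.isscalar(t):
            return np.full(self.n_subjects, int(t))
        t = np.asarray(t, dtype=int)
        if len(t) != self.n_subjects:
            raise ValueError("trials_per_subject list length != n_subjects")
        return t


def make_precision(
    p: int,
    edge_density: float,
    weight_range: tuple[float, float] = (0.1, 0.4),
    seed: int = 0,
    node_labels: list[str] | None = None,
    roles: dict[str, str] | None = None,
) -> PrecisionSpec:
    """Draw a sparse precision matrix with known partial correlations.

    The support is a G(p, m) random graph with ``m = round(density * C(p,2))``
    edges; edge partial-correlation magnitudes are uniform in ``weight_range``
    with independent Rademacher signs.  Positive-definiteness is enforced by
    boosting the diagonal until the smallest eigenvalue reaches 0.05, then
    rescaling back to a unit diagonal; a boost shrinks the realised partial
    correlations by the same factor, so ``true_partial_corr`` (not the drawn
    weights) is the ground truth to compare against.
    """
    if p < 3:
        raise ValueError("p must be >= 3")
    if not 0 <= edge_density < 1:
        raise ValueError("edge_density must be in [0, 1)")
    lo, hi = weight_range
    if not (0 < lo <= hi < 1):
        raise ValueError("weight_range must satisfy 0 < lo <= hi < 1")

    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    n_edges = int(round(edge_density * len(pairs)))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False) if n_edges else []

    theta = np.eye(p)
    for k in chosen:
        i, j = pairs[k]
        w = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        # theta_ij = -rho_ij on the unit-diagonal scale
        theta[i, j] = theta[j, i] = -w

    eigmin = float(np.linalg.eigvalsh(theta)[0])
    if eigmin < _MIN_EIG:
        delta = _MIN_EIG - eigmin
        if delta > _MAX_BOOST:
            raise ValueError(
                f"cannot reach positive-definiteness: required boost {delta:.3g} "
                f"exceeds limit {_MAX_BOOST}"
            )
        theta[np.diag_indices(p)] += delta
        theta /= 1.0 + delta  # back to unit diagonal; shrinks partial corrs

    if node_labels is None:
        node_labels = [f"v{i:02d}" for i in range(p)]
    if roles is None:
        roles = {lab: "trait" for lab in node_labels}
    return PrecisionSpec(node_labels=node_labels, roles=roles, theta=theta)


def sample_mvn(
    spec: PrecisionSpec,
    n: int,
    seed: int = 0,
    skew: dict | None = None,
) -> DataTable:
    """Sample ``n`` subjects from the zero-mean Gaussian with precision ``theta``.

    Parameters
    ----------
    skew : dict, optional
        ``{"columns": [names], "kind": "exp"}`` applies a strictly monotone
        elementwise transform to the named columns to induce marginal skewness
        (for exercising Box-Cox); ``kind`` may be ``exp`` (right skew) or
        ``neg_exp`` (left skew).  Rank correlations are unchanged.
    """
    rng = np.random.default_rng(seed)
    cov = spec.covariance()
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, spec.p))
    x = z @ chol.T
    df = pd.DataFrame(x, columns=spec.node_labels)
    df.index = [f"s{i:04d}" for i in range(n)]
    if skew is not None:
        kind = skew.get("kind", "exp")
        for col in skew["columns"]:
            if kind == "exp":
                df[col] = np.exp(df[col])
            elif kind == "neg_exp":
                df[col] = -np.exp(-df[col])
            else:
                raise ValueError(f"unknown skew kind {kind!r}")
    return DataTable(df, dict(spec.roles))


def _component_shape(times: np.ndarray, latency: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((times - latency) / sd) ** 2)


def make_epochs(spec: EpochSpec) -> EpochSet:
    """Generate trial-level epochs with known per-subject amplitude/latency.

    Per subject i a latent amplitude ``a_i ~ N(amp_mean, amp_sd_between^2)``
    and latency ``l_i ~ N(latency_mean, latency_sd^2)`` (truncated to the
    component window) are drawn; each trial is
    ``(a_i + N(0, amp_sd_within^2)) * gauss(t; l_i, component_sd)`` plus white
    noise.  The generating values are attached as ``truth``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.epoch_window
    n_samp = int(round((hi - lo) * spec.sampling_rate / 1000.0)) + 1
    times = lo + np.arange(n_samp) * 1000.0 / spec.sampling_rate

    counts = spec.trial_counts()
    amps = rng.normal(spec.amp_mean, spec.amp_sd_between, size=spec.n_subjects)
    lats = rng.normal(spec.latency_mean, spec.latency_sd, size=spec.n_subjects)
    lats = np.clip(lats, spec.component_window[0], spec.component_window[1])

    ids, eps = [], []
    for i in range(spec.n_subjects):
        shape = _component_shape(times, lats[i], spec.component_sd)
        trial_amp = amps[i] + rng.normal(0.0, spec.amp_sd_within, size=counts[i])
        sig = trial_amp[:, None] * shape[None, :]
        if spec.noise_sd > 0:
            sig = sig + rng.normal(0.0, spec.noise_sd, size=sig.shape)
        ids.append(f"s{i:04d}")
        eps.append(sig)

    return EpochSet(
        subject_ids=ids,
        epochs=eps,
        times=times,
        sampling_rate=spec.sampling_rate,
        condition=spec.condition,
        truth={"amplitude": amps, "latency": lats, "n_trials": counts},
    )


def make_study(
    p_traits: int = 30,
    n_train: int = 236,
    n_test: int = 107,
    seed: int = 0,
    edge_density: float = 0.10,
    weight_range: tuple[float, float] = (0.05, 0.45),
    skew_traits: int = 0,
) -> tuple[DataTable, DataTable, PrecisionSpec]:
    """Emulate the study design: traits + ERN + CRN + covariates, split in two.

    One precision structure is drawn over ``p_traits`` trait nodes, two ERP
    amplitude nodes (ERN, CRN), two ERP latency covariates and two scalar
    covariates (age, performance); independent training and testing samples of
    the requested sizes are drawn from the same population.  Defaults mirror a
    mid-size individual-differences ERP study: ~30 questionnaire scales, a
    236/107 train/test split, and partial correlations up to ~.45.

    ``skew_traits`` > 0 applies a monotone exponential transform to that many
    trait columns so the transform stage has work to do.
    """
    if min(p_traits, n_train, n_test) <= 0:
        raise ValueError("counts must be positive")
    labels = [f"trait_{i:02d}" for i in range(p_traits)] + [
        "ERN", "CRN", "ern_latency", "crn_latency", "age", "performance",
    ]
    roles = {lab: "trait" for lab in labels[:p_traits]}
    roles.update(
        ERN="erp_amplitude", CRN="erp_amplitude",
        ern_latency="erp_latency", crn_latency="erp_latency",
        age="covariate", performance="covariate",
    )
    spec = make_precision(
        len(labels), edge_density, weight_range, seed=seed,
        node_labels=labels, roles=roles,
    )
    skew = None
    if skew_traits:
        skew = {"columns": labels[:skew_traits], "kind": "exp"}
    # derive independent child seeds; keep them in int32 range
    ss = np.random.SeedSequence(seed).spawn(2)
    s_train, s_test = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss)
    train = sample_mvn(spec, n_train, seed=s_train, skew=skew)
    test = sample_mvn(spec, n_test, seed=s_test, skew=skew)
    return train, test, spec
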