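"""Three-compartment attenuation model of the lung parenchyma.

The lungs of a CTEPH patient are modelled as a mixture of three Gaussian
attenuation compartments: oligemic (low HU, hypoperfused), normal, and
hyperemic (high HU, hyperperfused).  A Gaussian mixture is fitted to the
pooled voxel attenuation samples of *both* lungs by variational Bayesian
estimation, the components are ordered by mean and mapped to the three
compartments, and every lung voxel is then MAP-classified with the fitted
parameters.  Each compartment's headline "proportion" is its mixture
weight; voxel-count fractions from the classification mask are reported
alongside for QC.

Fitting is deterministic: component means are initialized at the
10th/50th/90th percentiles of the samples with equal weights, so repeated
runs with the same configuration and seed give bit-identical parameters.
The seed only governs the optional subsampling used for very large lungs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.mixture import BayesianGaussianMixture

from .imaging import CTVolume, QCWarning, SegmentationSet, DEFAULT_CLIP_RANGE

__all__ = [
    "GaussianComponent",
    "AttenuationModel",
    "CompartmentMask",
    "Proportions",
    "COMPARTMENT_LABELS",
    "fit_three_component_model",
    "classify_voxels",
    "compartment_proportions",
]

#: Label codes of the classification mask.
COMPARTMENT_LABELS = {0: "background", 1: "oligemic", 2: "normal", 3: "hyperemic"}

_HARD_MIN_SAMPLES = 30
_SOFT_MIN_SAMPLES = 10_000
#: Lungs larger than this are subsampled (seeded) for fitting only;
#: classification always uses the full volume.
DEFAULT_SUBSAMPLE_CAP = 2_000_000


@dataclass(frozen=True)
class GaussianComponent:
    weight: float
    mean: float   # HU
    sd: float     # HU


@dataclass(frozen=True)
class AttenuationModel:
    """Fitted three-component attenuation mixture, ordered low -> high mean.

    Component 0 is the oligemic compartment, 1 normal, 2 hyperemic.
    """

    components: tuple[GaussianComponent, GaussianComponent, GaussianComponent]
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.array([c.weight for c in self.components])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must be >= 0 and sum to 1, got {w}")
        if any(c.sd <= 0 for c in self.components):
            raise ValueError("component SDs must be positive")
        means = [c.mean for c in self.components]
        if not (means[0] <= means[1] <= means[2]):
            raise ValueError(f"components must be ordered by mean, got {means}")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c.sd for c in self.components])

    def log_weighted_density(self, x: np.ndarray) -> np.ndarray:
        """log(weight_k * N(x; mean_k, sd_k)) for each component, shape (n, 3).

        Components with zero weight get -inf so they can never win MAP.
        """
        x = np.asarray(x, dtype=float)[:, None]
        w, mu, sd = self.weights[None, :], self.means[None, :], self.sds[None, :]
        with np.errstate(divide="ignore"):
            logw = np.log(w)
        return logw - np.log(sd) - 0.5 * np.log(2 * np.pi) - 0.5 * ((x - mu) / sd) ** 2


@dataclass(frozen=True)
class CompartmentMask:
    """Per-voxel compartment labels: 0 background, 1 oligemic, 2 normal, 3 hyperemic."""

    labels: np.ndarray  # uint8, CT shape

    def counts(self) -> dict[str, int]:
        return {name: int(np.count_nonzero(self.labels == code))
                for code, name in COMPARTMENT_LABELS.items() if code}


@dataclass(frozen=True)
class Proportions:
    oligemic: float
    normal: float
    hyperemic: float
    source: str  # "mixture_weights" | "voxel_counts"

    def __post_init__(self) -> None:
        vals = (self.oligemic, self.normal, self.hyperemic)
        if any(not (0 <= v <= 1) for v in vals):
            raise ValueError(f"proportions must lie in [0, 1], got {vals}")
        if abs(sum(vals) - 1.0) > 1e-6:
            raise ValueError(f"proportions must sum to 1, got {sum(vals)}")

    def as_dict(self) -> dict[str, float]:
        return {"oligemic": self.oligemic, "normal": self.normal,
                "hyperemic": self.hyperemic}


class _PercentileInitVBGMM(BayesianGaussianMixture):
    """VB Gaussian mixture with deterministic percentile initialization.

    Responsibilities are initialized from equal-weight Gaussians centred at
    the 2nd/50th/98th sample percentiles — wide anchors so a minority
    compartment of a few percent still attracts its own component in lungs
    dominated by normal parenchyma.  The init SD is a quarter of the pooled
    SD: sharp enough to break symmetry quickly (and at all, for degenerate
    near-constant input, where the anchors are nudged apart
    deterministically).
    """

    def _initialize_parameters(self, X, random_state, xp=None):  # noqa: N803
        x = np.asarray(X)[:, 0]
        mus = np.percentile(x, [2.0, 50.0, 98.0]).astype(float)
        pooled_sd = max(float(x.std()), 1e-2)
        if not (mus[0] < mus[1] < mus[2]):
            mus = mus + np.array([-1.0, 0.0, 1.0]) * max(1e-3, 0.05 * pooled_sd)
        s0 = max(0.25 * pooled_sd, 1e-2)
        log_resp = -0.5 * ((x[:, None] - mus[None, :]) / s0) ** 2
        log_resp -= logsumexp(log_resp, axis=1, keepdims=True)
        self._lower_bound_trace: list[float] = []
        self._initialize(np.asarray(X), np.exp(log_resp))

    def _compute_lower_bound(self, log_resp, log_prob_norm):
        lb = super()._compute_lower_bound(log_resp, log_prob_norm)
        trace = getattr(self, "_lower_bound_trace", None)
        if trace is not None:
            trace.append(float(lb))
        return lb


def fit_three_component_model(samples: np.ndarray, *,
                              max_iter: int = 500, tol: float = 1e-4,
                              weight_concentration_prior: float = 1.0 / 3.0,
                              subsample_cap: int = DEFAULT_SUBSAMPLE_CAP,
                              seed: int = 0) -> AttenuationModel:
    """Fit the three-component attenuation mixture to pooled both-lung samples.

    Parameters
    ----------
    samples
        1-D array of HU values, pooled over both lungs (within clip range).
    max_iter, tol
        Variational EM iteration cap and evidence-lower-bound tolerance.
    weight_concentration_prior
        Symmetric Dirichlet concentration; the weakly sparsifying default
        1/3 lets a component vanish gracefully in near-unimodal lungs.
    subsample_cap
        Seeded uniform subsample size used for fitting when the lung is
        larger; classification is unaffected.
    seed
        Governs only the subsampling draw.

    Raises
    ------
    ValueError
        If fewer than 30 samples are supplied.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < _HARD_MIN_SAMPLES:
        raise ValueError(
            f"need at least {_HARD_MIN_SAMPLES} samples to fit, got {len(x)}"
        )
    if len(x) < _SOFT_MIN_SAMPLES:
        warnings.warn(
            f"only {len(x)} attenuation samples (< {_SOFT_MIN_SAMPLES}); "
            "mixture estimates may be noisy",
            QCWarning,
            stacklevel=2,
        )
    n_total = len(x)
    if n_total > subsample_cap:
        rng = np.random.default_rng(seed)
        x = x[rng.choice(n_total, size=subsample_cap, replace=False)]

    est = _PercentileInitVBGMM(
        n_components=3,
        covariance_type="full",
        weight_concentration_prior=weight_concentration_prior,
        mean_prior=[float(x.mean())],
        mean_precision_prior=1e-2,
        covariance_prior=np.atleast_2d(max(float(x.var()), 1.0)),
        max_iter=max_iter,
        tol=tol,
        reg_covar=1e-6,
    )
    with warnings.catch_warnings():
        # non-convergence is reported via fit_info, not sklearn's warning
        warnings.simplefilter("ignore")
        est.fit(x.reshape(-1, 1))
    if not est.converged_:
        warnings.warn(
            f"attenuation mixture did not converge in {max_iter} iterations",
            QCWarning,
            stacklevel=2,
        )

    means = est.means_[:, 0]
    sds = np.sqrt(est.covariances_[:, 0, 0])
    weights = est.weights_
    order = np.argsort(means, kind="stable")  # ties: lower index wins
    weights = weights[order] / weights.sum()
    comps = tuple(
        GaussianComponent(weight=float(w), mean=float(m), sd=float(s))
        for w, m, s in zip(weights, means[order], sds[order])
    )
    fit_info = {
        "n_samples_used": int(len(x)),
        "n_samples_total": int(n_total),
        "n_iterations": int(est.n_iter_),
        "converged": bool(est.converged_),
        "lower_bound_trace": list(getattr(est, "_lower_bound_trace", [])),
    }
    return AttenuationModel(components=comps, fit_info=fit_info)


def classify_voxels(volume: CTVolume, seg: SegmentationSet,
                    model: AttenuationModel,
                    clip_range: tuple[float, float] = DEFAULT_CLIP_RANGE
                    ) -> CompartmentMask:
    """MAP-classify every in-window lung voxel into a compartment.

    Each voxel is assigned the component maximizing weight x Gaussian
    density at its HU value; exact ties go to the lower-mean component.
    Voxels outside the lungs or the clip range keep label 0.
    """
    lo, hi = clip_range
    in_scope = seg.lungs & (volume.data >= lo) & (volume.data <= hi)
    labels = np.zeros(volume.shape, dtype=np.uint8)
    x = volume.data[in_scope].astype(float)
    if len(x):
        ll = model.log_weighted_density(x)
        labels[in_scope] = np.argmax(ll, axis=1).astype(np.uint8) + 1
    return CompartmentMask(labels=labels)


def compartment_proportions(model: AttenuationModel, mask: CompartmentMask
                            ) -> tuple[Proportions, Proportions]:
    """Relative compartment proportions from mixture weights and voxel counts.

    The weight-based proportions are the headline metric (the compartment's
    relative proportion in the attenuation histogram); count-based fractions
    from the MAP mask are the QC companion.
    """
    w = model.weights
    w = w / w.sum()
    by_weight = Proportions(oligemic=float(w[0]), normal=float(w[1]),
                            hyperemic=float(w[2]), source="mixture_weights")
    counts = np.array([np.count_nonzero(mask.labels == c) for c in (1, 2, 3)],
                      dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("classification mask has no labelled voxels")
    f = counts / total
    by_count = Proportions(oligemic=float(f[0]), normal=float(f[1]),
                           hyperemic=float(f[2]), source="voxel_counts")
    return by_weight, by_count
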