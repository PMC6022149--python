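"""Per-class multivariate Gaussian classifiers and the training pipeline.

One multivariate Gaussian density (MGD) is fitted per activity class
(maximum-likelihood mean and covariance, divisor m).  A new window is
assigned the class with the largest density; falls — which never appear
in training data — are flagged as anomalies of the vigorous-activity
model: a window whose best class is VIA is a fall only when its VIA
density drops below a threshold eps2 AND its tilt angle exceeds eps3
degrees.  All density work happens in log space (Cholesky) so that
13-dimensional densities neither overflow nor underflow.

``train_personalized`` runs the full adaptation pipeline on a new
user's raw, unlabeled stream: filtering/segmentation -> features ->
seeded K-Means annotation (centroids from a pre-labeled dataset) ->
LLOF confidence filtering -> per-class MGD fits -> threshold
calibration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg
from scipy.stats import chi2

from .features import (
    TA_INDEX,
    Normalizer,
    apply_normalizer,
    feature_matrix,
    fit_normalizer,
)
from .io_calibration import RawStream
from .llof import LLOFParams, filter_outliers
from .preprocessing import preprocess_stream
from .seeded_kmeans import (
    ACTIVITY_CLASSES,
    LabeledFeatureSet,
    kmeans_annotate,
    seed_centroids,
)

FALL_LABEL = "Fall"

_LOG_2PI = float(np.log(2.0 * np.pi))


def _regularize(sigma: np.ndarray) -> np.ndarray:
    """Symmetrize and, if near-singular, add lam*I with
    lam = 1e-6 * trace/n (floor 1e-8), repeated up to 10 times."""
    sigma = np.asarray(sigma, dtype=float)
    sigma = 0.5 * (sigma + sigma.T)
    n = sigma.shape[0]
    for _ in range(10):
        eigvals = np.linalg.eigvalsh(sigma)
        if eigvals[0] > 1e-10 * max(eigvals[-1], np.finfo(float).tiny):
            return sigma
        lam = max(1e-6 * np.trace(sigma) / n, 1e-8)
        sigma = sigma + lam * np.eye(n)
    return sigma


@dataclass
class MGDModel:
    """Gaussian of one activity class with cached Cholesky factor."""

    mu: np.ndarray
    sigma: np.ndarray
    label: str = ""
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)
    _logdet: float = field(default=0.0, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (len(self.mu), len(self.mu)):
            raise ValueError("sigma must be square and match mu")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        self._chol = linalg.cholesky(self.sigma, lower=True)
        self._logdet = 2.0 * float(np.sum(np.log(np.diag(self._chol))))

    @property
    def dim(self) -> int:
        return len(self.mu)

    def logpdf(self, x: np.ndarray) -> np.ndarray | float:
        """Log density; accepts a single vector or an (m, n) matrix."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("density requested at non-finite point")
        single = x.ndim == 1
        pts = np.atleast_2d(x) - self.mu
        z = linalg.solve_triangular(self._chol, pts.T, lower=True)
        maha = np.sum(z * z, axis=0)
        out = -0.5 * (self.dim * _LOG_2PI + self._logdet + maha)
        return float(out[0]) if single else out

    def pdf(self, x: np.ndarray) -> np.ndarray | float:
        return np.exp(self.logpdf(x))


def fit_mgd(samples: np.ndarray, label: str = "") -> MGDModel:
    """Maximum-likelihood Gaussian fit (covariance divisor m), regularized
    to positive definiteness when near-singular."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or len(samples) < 2:
        raise ValueError("fit_mgd requires at least 2 samples")
    mu = samples.mean(axis=0)
    centered = samples - mu
    sigma = centered.T @ centered / len(samples)
    return MGDModel(mu=mu, sigma=_regularize(sigma), label=label)


def mgd_density(model: MGDModel, x: np.ndarray) -> float:
    """Density value p(x) = (2pi)^(-n/2) |Sigma|^(-1/2) exp(-maha/2)."""
    return float(np.exp(model.logpdf(np.asarray(x, dtype=float))))


@dataclass
class PersonalizedClassifier:
    """Three class Gaussians + fall thresholds + the training normalizer.

    ``log_eps2`` is the VIA density threshold stored in log space (its
    linear-scale value in 13 dimensions can under/overflow); ``eps3_deg``
    is the tilt-angle threshold in degrees, compared against the raw
    (un-normalized) tilt angle.
    """

    models: tuple[MGDModel, MGDModel, MGDModel]   # order LIA, MIA, VIA
    log_eps2: float
    eps3_deg: float
    normalizer: Normalizer
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(m.label for m in self.models) != ACTIVITY_CLASSES:
            raise ValueError(f"models must be ordered {ACTIVITY_CLASSES}")
        if not self.eps3_deg > 0:
            raise ValueError("eps3 must be > 0")

    @property
    def eps2(self) -> float:
        return float(np.exp(self.log_eps2))

    def log_densities(self, X_raw: np.ndarray) -> np.ndarray:
        """(m, 3) log densities of raw feature vectors under the class models."""
        Z = apply_normalizer(self.normalizer, np.atleast_2d(X_raw))
        return np.column_stack([m.logpdf(Z) for m in self.models])

    def classify(self, X_raw: np.ndarray) -> np.ndarray:
        """Vectorized `classify_window` over raw (un-normalized) features."""
        X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
        logp = self.log_densities(X_raw)
        best = np.argmax(logp, axis=1)  # ties -> lowest index (LIA > MIA > VIA)
        ta = X_raw[:, TA_INDEX]
        out = np.empty(len(X_raw), dtype=object)
        for i, k in enumerate(best):
            if k < 2:
                out[i] = ACTIVITY_CLASSES[k]
            elif logp[i, 2] <= self.log_eps2 and ta[i] >= self.eps3_deg:
                out[i] = FALL_LABEL
            else:
                out[i] = ACTIVITY_CLASSES[2]
        return out


def classify_window(clf: PersonalizedClassifier, fv_raw: np.ndarray) -> str:
    """Activity label for one raw feature vector.

    The vector is normalized with the classifier's training normalizer;
    the fall rule thresholds the raw tilt angle (element ``TA_INDEX``)
    in degrees.  A window is a fall only when the VIA model both wins
    the argmax and rejects it (density <= eps2) while the tilt angle
    exceeds eps3.
    """
    return str(clf.classify(np.asarray(fv_raw, dtype=float)[None, :])[0])


def calibrate_thresholds(
    via_model: MGDModel,
    via_training_norm: np.ndarray,
    eps2_percentile: float = 1.0,
    eps3_deg: float = 60.0,
    eps2_override: float | None = None,
    min_windows: int = 20,
) -> tuple[float, float]:
    """Return (log_eps2, eps3_deg).

    eps2 is the ``eps2_percentile``-th percentile of the VIA model's
    density over the normalized VIA training windows (computed in log
    space; percentiles commute with the monotone log).  With fewer than
    ``min_windows`` VIA windows the threshold falls back to
    ``eps2_override`` if given, else to the density on the 99.9%
    chi-square Mahalanobis contour of the fitted Gaussian.
    """
    via_training_norm = np.atleast_2d(np.asarray(via_training_norm, dtype=float))
    if len(via_training_norm) < min_windows:
        warnings.warn(
            f"only {len(via_training_norm)} VIA windows; using fallback eps2",
            stacklevel=2,
        )
        if eps2_override is not None:
            return float(np.log(eps2_override)), float(eps3_deg)
        peak = float(via_model.logpdf(via_model.mu))
        return peak - 0.5 * float(chi2.ppf(0.999, df=via_model.dim)), float(eps3_deg)
    logp = np.asarray(via_model.logpdf(via_training_norm), dtype=float)
    return float(np.percentile(logp, eps2_percentile)), float(eps3_deg)


def train_personalized(
    stream: RawStream,
    seed_X: np.ndarray,
    seed_y: np.ndarray,
    *,
    rate_hz: float | None = None,
    gravity_cutoff_hz: float = 0.3,
    butter_order: int = 3,
    window_s: float = 1.0,
    overlap: float = 0.5,
    kmeans_max_iter: int = 100,
    llof_k: int = 20,
    llof_eps1: float = 1.5,
    eps2_percentile: float = 1.0,
    eps3_deg: float = 60.0,
    eps2_override: float | None = None,
) -> tuple[PersonalizedClassifier, dict]:
    """Full adaptation pipeline on an unlabeled, fall-free user stream.

    ``seed_X``/``seed_y`` are pre-labeled raw feature vectors from other
    users; only their class centroids enter the model (K-Means seeding).
    Each dataset is min-max normalized on its own for the annotation
    step — the seed centroids live in the seed data's normalized space,
    the user's windows in theirs — which cancels per-subject gain
    differences so the labeled centroids land near the user's clusters.
    The normalizer is then refitted on the user's retained windows alone
    for the Gaussians.

    Returns the classifier and a training report (iterations, removal
    counts, per-class sizes).
    """
    if rate_hz is not None and rate_hz != stream.rate_hz:
        stream = RawStream(stream.data, rate_hz=rate_hz, labels=stream.labels)

    windows = preprocess_stream(
        stream,
        cutoff_hz=gravity_cutoff_hz,
        order=butter_order,
        window_s=window_s,
        overlap=overlap,
    )
    user_X, _ = feature_matrix(windows)
    seed_X = np.asarray(seed_X, dtype=float)

    # annotation: each dataset normalized on its own scale
    seed_norm = fit_normalizer(seed_X)
    annot_norm = fit_normalizer(user_X)
    seeds = seed_centroids(seed_norm.transform(seed_X), seed_y)
    km = kmeans_annotate(annot_norm.transform(user_X), seeds, max_iter=kmeans_max_iter)

    # LLOF in the same normalized space the clustering ran in
    annotated_norm = LabeledFeatureSet(km.labeled.X, km.labeled.y, provenance="annotated")
    _, _, scores = filter_outliers(
        annotated_norm, LLOFParams(k_neighbors=llof_k, eps1=llof_eps1)
    )
    keep_mask = scores <= llof_eps1
    kept_raw = user_X[keep_mask]
    kept_labels = km.labeled.y[keep_mask]

    # model space: min-max refitted on the user's own retained windows
    user_norm = fit_normalizer(kept_raw)
    Z = user_norm.transform(kept_raw)
    models = []
    class_sizes = {}
    for cls in ACTIVITY_CLASSES:
        mask = np.array([str(lab) == cls for lab in kept_labels])
        class_sizes[cls] = int(mask.sum())
        if class_sizes[cls] < 2:
            raise ValueError(
                f"class {cls!r} has {class_sizes[cls]} samples after filtering; "
                "cannot fit its Gaussian"
            )
        models.append(fit_mgd(Z[mask], label=cls))

    via_mask = np.array([str(lab) == ACTIVITY_CLASSES[2] for lab in kept_labels])
    log_eps2, eps3 = calibrate_thresholds(
        models[2],
        Z[via_mask],
        eps2_percentile=eps2_percentile,
        eps3_deg=eps3_deg,
        eps2_override=eps2_override,
    )

    report = {
        "n_windows": len(user_X),
        "kmeans_iterations": km.n_iter,
        "kmeans_converged": km.converged,
        "n_removed": int((~keep_mask).sum()),
        "class_sizes": class_sizes,
        "llof_k": llof_k,
        "llof_eps1": llof_eps1,
        "eps2_percentile": eps2_percentile,
        "eps3_deg": eps3,
    }
    clf = PersonalizedClassifier(
        models=tuple(models),
        log_eps2=log_eps2,
        eps3_deg=eps3,
        normalizer=user_norm,
        meta=report,
    )
    return clf, report


# --- serialization -------------------------------------------------------

def classifier_to_json(clf: PersonalizedClassifier) -> str:
    doc = {
        "models": [
            {"label": m.label, "mu": m.mu.tolist(), "sigma": m.sigma.tolist()}
            for m in clf.models
        ],
        "log_eps2": clf.log_eps2,
        "eps3_deg": clf.eps3_deg,
        "normalizer": {
            "min": clf.normalizer.min_.tolist(),
            "scale": clf.normalizer.scale_.tolist(),
            "method": clf.normalizer.method,
        },
        "meta": clf.meta,
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def classifier_from_json(text: str) -> PersonalizedClassifier:
    doc = json.loads(text)
    models = tuple(
        MGDModel(mu=np.array(m["mu"]), sigma=np.array(m["sigma"]), label=m["label"])
        for m in doc["models"]
    )
    norm = Normalizer(
        min_=np.array(doc["normalizer"]["min"]),
        scale_=np.array(doc["normalizer"]["scale"]),
        method=doc["normalizer"]["method"],
    )
    return PersonalizedClassifier(
        models=models,
        log_eps2=float(doc["log_eps2"]),
        eps3_deg=float(doc["eps3_deg"]),
        normalizer=norm,
        meta=doc.get("meta", {}),
    )


def save_classifier(clf: PersonalizedClassifier, path: str | Path) -> None:
    Path(path).write_text(classifier_to_json(clf))


def load_classifier(path: str | Path) -> PersonalizedClassifier:
    return classifier_from_json(Path(path).read_text())
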