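"""Receptivity classification by PCA projection and Mahalanobis distance.

The reference model is fitted on a development set spanning the natural
cycle: molecule counts are housekeeper-normalized, z-scored with
development-set parameters, and decomposed by PCA.  Horn's parallel
analysis (eigenvalues of column-permuted data) decides how many
components to keep.  Phase labels collapse to three reference classes
(PE/ESE -> pre-receptive, MSE -> receptive, LSE -> post-receptive); a
class centroid and a pooled within-class covariance are computed in the
retained component space.

A test sample is projected with the stored eigenvectors and scaling
(never its own), and its squared Mahalanobis distance to each reference
centroid is computed.  Under the Gaussian model d² ~ chi²(k), which
yields per-class outlier tail probabilities (alpha = 0.025).  The final
call is hierarchical: the closest reference class selects a temporally
adjacent pair of classes, the pair's relative probabilities follow from
the Gaussian kernel exp(-d²/2), and a sample whose leading probability
falls between the decision boundaries (default 0.25/0.75) is assigned
the transitionary class between the pair (early- or late-receptive).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .panel_io import (
    PHASE_TO_CLASS,
    REFERENCE_CLASSES,
    TRANSITION_BETWEEN,
    CountMatrix,
    ReceptivityClass,
)
from .preprocess import (
    NormalizedMatrix,
    ScalingParams,
    apply_scaling,
    fit_scaling,
    normalize_housekeepers,
    shifted_log,
)

log = logging.getLogger(__name__)

MODEL_FORMAT = "beready-model"
MODEL_VERSION = 1

#: The temporally adjacent reference-class pairs.
ADJACENT_PAIRS = (
    (ReceptivityClass.PRE, ReceptivityClass.RECEPTIVE),
    (ReceptivityClass.RECEPTIVE, ReceptivityClass.POST),
)


# ---------------------------------------------------------------------------
# PCA + Horn's parallel analysis
# ---------------------------------------------------------------------------

def _pca_eigvals(X: np.ndarray) -> np.ndarray:
    """Sample-covariance eigenvalues of a column-centered matrix."""
    n = X.shape[0]
    s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    lam = np.zeros(min(X.shape))
    lam[: len(s)] = s**2 / (n - 1)
    return lam


def horn_parallel(X: np.ndarray, n_iter: int = 100, quantile: float = 0.05,
                  seed: int | np.random.Generator | None = None) -> int:
    """Number of PCA components to retain by Horn's parallel analysis.

    The null eigenvalue distribution comes from ``n_iter`` copies of the
    data with each column independently permuted (preserving marginal
    distributions while destroying correlation).  Component j is retained
    while its observed eigenvalue exceeds the (1 - quantile) empirical
    quantile of the j-th null eigenvalue; counting stops at the first
    failure.  A floor of k = 1 is enforced.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows and columns")
    if not (0 < quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate rank-0 matrix")
    rng = np.random.default_rng(seed)
    obs = _pca_eigvals(X)
    n, g = X.shape
    null = np.empty((n_iter, len(obs)))
    perm = np.empty_like(X)
    for i in range(n_iter):
        for j in range(g):
            perm[:, j] = X[rng.permutation(n), j]
        null[i] = _pca_eigvals(perm)
    thresh = np.quantile(null, 1.0 - quantile, axis=0)
    k = 0
    for lam, t in zip(obs, thresh):
        if lam > t:
            k += 1
        else:
            break
    return max(k, 1)


# ---------------------------------------------------------------------------
# Distances and probabilities
# ---------------------------------------------------------------------------

def mahalanobis_sq(x: np.ndarray, centroid: np.ndarray, cov_inv: np.ndarray) -> float:
    """Squared Mahalanobis distance (x - c)' S^-1 (x - c)."""
    x = np.asarray(x, dtype=float)
    c = np.asarray(centroid, dtype=float)
    ci = np.asarray(cov_inv, dtype=float)
    if x.shape != c.shape or ci.shape != (x.size, x.size):
        raise ValueError(
            f"dimension mismatch: x {x.shape}, centroid {c.shape}, cov_inv {ci.shape}"
        )
    d = x - c
    return float(d @ ci @ d)


def outlier_p(d2: float, k: int, alpha: float = 0.025,
              tail: str = "upper") -> tuple[float, bool]:
    """Chi-square tail probability of a squared Mahalanobis distance.

    ``tail="upper"`` (default) flags samples far from the centroid;
    ``"lower"`` flags implausibly close ones; ``"both"`` flags either
    (each tail tested at alpha).  Returns (p, is_outlier).
    """
    if d2 < 0 or k < 1:
        raise ValueError("require d2 >= 0 and k >= 1")
    upper = float(stats.chi2.sf(d2, df=k))
    lower = float(stats.chi2.cdf(d2, df=k))
    if tail == "upper":
        return upper, upper < alpha
    if tail == "lower":
        return lower, lower < alpha
    if tail == "both":
        p = min(upper, lower)
        return p, p < alpha
    raise ValueError(f"unknown tail {tail!r}")


def relative_probability(d2_a: float, d2_b: float) -> tuple[float, float]:
    """Relative probability of membership in group a vs b under the
    Gaussian kernel exp(-d²/2), normalized over the pair.

    Computed through a logistic form, so it stays valid for arbitrarily
    large distances; p_a + p_b == 1 exactly.
    """
    if not (np.isfinite(d2_a) and np.isfinite(d2_b)) or d2_a < 0 or d2_b < 0:
        raise ValueError("distances must be finite and non-negative")
    p_a = float(expit((d2_b - d2_a) / 2.0))
    return p_a, 1.0 - p_a


# ---------------------------------------------------------------------------
# Reference model
# ---------------------------------------------------------------------------

@dataclass
class ReferenceModel:
    """Fitted development-set model: scaling, retained eigenvectors, class
    centroids and pooled within-class covariance in component space."""

    scaling: ScalingParams
    housekeeper_ids: tuple[str, ...]
    eigenvectors: pd.DataFrame        # genes x k
    eigenvalues: np.ndarray           # all development eigenvalues
    k: int
    centroids: dict[ReceptivityClass, np.ndarray]
    within_cov: np.ndarray            # k x k, ridge-regularized
    within_cov_inv: np.ndarray
    ridge_eps: float
    outlier_alpha: float = 0.025
    outlier_tail: str = "upper"
    log_before_scale: bool = False
    class_order: tuple = REFERENCE_CLASSES
    version: int = MODEL_VERSION

    # -- projection ------------------------------------------------------
    def transform(self, m: CountMatrix) -> tuple[pd.DataFrame, NormalizedMatrix]:
        """Normalize, (optionally log,) scale with stored parameters and
        project onto the retained eigenvectors.  Returns (scores, scaled)."""
        nm = normalize_housekeepers(m, self.housekeeper_ids)
        if self.log_before_scale:
            nm = shifted_log(nm)
        scaled = apply_scaling(nm, self.scaling)
        scores = scaled.values @ self.eigenvectors
        return scores, scaled

    # -- persistence -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": MODEL_FORMAT,
            "version": self.version,
            "housekeeper_ids": list(self.housekeeper_ids),
            "scaling": {
                "gene_ids": self.scaling.gene_ids,
                "center": self.scaling.center.tolist(),
                "scale": self.scaling.scale.tolist(),
                "dropped": list(self.scaling.dropped),
            },
            "eigenvectors": self.eigenvectors.to_numpy().tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "k": self.k,
            "class_order": [c.value for c in self.class_order],
            "centroids": {c.value: v.tolist() for c, v in self.centroids.items()},
            "within_cov": self.within_cov.tolist(),
            "ridge_eps": self.ridge_eps,
            "outlier_alpha": self.outlier_alpha,
            "outlier_tail": self.outlier_tail,
            "log_before_scale": self.log_before_scale,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceModel":
        if d.get("format") != MODEL_FORMAT:
            raise ValueError(f"not a {MODEL_FORMAT} file (format={d.get('format')!r})")
        if d.get("version") != MODEL_VERSION:
            raise ValueError(
                f"model version {d.get('version')!r} not supported "
                f"(this build reads version {MODEL_VERSION})"
            )
        genes = d["scaling"]["gene_ids"]
        scaling = ScalingParams(
            center=pd.Series(d["scaling"]["center"], index=genes),
            scale=pd.Series(d["scaling"]["scale"], index=genes),
            dropped=tuple(d["scaling"]["dropped"]),
        )
        within = np.asarray(d["within_cov"])
        return cls(
            scaling=scaling,
            housekeeper_ids=tuple(d["housekeeper_ids"]),
            eigenvectors=pd.DataFrame(np.asarray(d["eigenvectors"]), index=genes),
            eigenvalues=np.asarray(d["eigenvalues"]),
            k=int(d["k"]),
            centroids={
                ReceptivityClass(c): np.asarray(v) for c, v in d["centroids"].items()
            },
            within_cov=within,
            within_cov_inv=np.linalg.inv(within),
            ridge_eps=float(d["ridge_eps"]),
            outlier_alpha=float(d["outlier_alpha"]),
            outlier_tail=d["outlier_tail"],
            log_before_scale=bool(d["log_before_scale"]),
            class_order=tuple(ReceptivityClass(c) for c in d["class_order"]),
            version=int(d["version"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceModel":
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as e:
            raise ValueError(f"cannot parse model file {path}: {e}") from e
        return cls.from_dict(d)


def fit_reference(dev: CountMatrix, housekeepers=None, *, n_iter: int = 100,
                  quantile: float = 0.05, ridge: float = 1e-6,
                  outlier_alpha: float = 0.025, outlier_tail: str = "upper",
                  log_before_scale: bool = False,
                  seed: int | None = None) -> ReferenceModel:
    """Fit the reference model on a labelled development set.

    ``housekeepers`` defaults to nothing sensible — pass the panel's
    housekeeper gene IDs.  Horn's permutations are driven by ``seed``;
    everything else is deterministic, so the whole fit is reproducible.
    """
    if housekeepers is None:
        raise ValueError("housekeeper gene IDs are required")
    labels = dev.reference_labels()
    if labels.isna().any():
        bad = list(labels.index[labels.isna()])
        raise ValueError(
            f"training requires phase labels in {list(PHASE_TO_CLASS)}; "
            f"missing/unknown for {bad}"
        )
    nm = normalize_housekeepers(dev, housekeepers)
    labels = labels.loc[nm.sample_ids]
    for cls_ in REFERENCE_CLASSES:
        n_c = int((labels == cls_).sum())
        if n_c < 2:
            raise ValueError(
                f"reference class {cls_.value!r} has {n_c} sample(s); need >= 2"
            )
    if log_before_scale:
        nm = shifted_log(nm)
    scaling = fit_scaling(nm)
    scaled = apply_scaling(nm, scaling)
    X = scaled.values.to_numpy()
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values after scaling")

    # PCA via SVD of the scaled matrix; deterministic eigenvector signs.
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / (n - 1)
    V = Vt.T
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    V = V * flip

    k = horn_parallel(X, n_iter=n_iter, quantile=quantile, seed=seed)
    eigenvectors = pd.DataFrame(V[:, :k], index=scaling.gene_ids)
    scores = X @ V[:, :k]

    centroids: dict[ReceptivityClass, np.ndarray] = {}
    pooled = np.zeros((k, k))
    dof = 0
    for cls_ in REFERENCE_CLASSES:
        member = scores[(labels == cls_).to_numpy()]
        centroids[cls_] = member.mean(axis=0)
        dm = member - centroids[cls_]
        pooled += dm.T @ dm
        dof += len(member) - 1
    within = pooled / dof
    eps = ridge * np.trace(within) / k
    within = within + eps * np.eye(k)
    return ReferenceModel(
        scaling=scaling,
        housekeeper_ids=tuple(housekeepers),
        eigenvectors=eigenvectors,
        eigenvalues=eigvals,
        k=k,
        centroids=centroids,
        within_cov=within,
        within_cov_inv=np.linalg.inv(within),
        ridge_eps=eps,
        outlier_alpha=outlier_alpha,
        outlier_tail=outlier_tail,
        log_before_scale=log_before_scale,
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    """Per-sample classifier output with all intermediates reported."""

    sample_id: str
    scores: np.ndarray
    d2: dict[ReceptivityClass, float]
    outlier_p: dict[ReceptivityClass, float]
    is_outlier: dict[ReceptivityClass, bool]
    overall_outlier: bool
    stage1_pair: tuple[ReceptivityClass, ReceptivityClass]
    stage2_pair: tuple[ReceptivityClass, ReceptivityClass]
    rel_prob: dict[ReceptivityClass, float]
    final_class: ReceptivityClass
    boundaries: tuple[float, float]
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "scores": self.scores.tolist(),
            "d2": {c.value: v for c, v in self.d2.items()},
            "outlier_p": {c.value: v for c, v in self.outlier_p.items()},
            "is_outlier": {c.value: v for c, v in self.is_outlier.items()},
            "overall_outlier": self.overall_outlier,
            "stage1_pair": [c.value for c in self.stage1_pair],
            "stage2_pair": [c.value for c in self.stage2_pair],
            "rel_prob": {c.value: v for c, v in self.rel_prob.items()},
            "final_class": self.final_class.value,
            "boundaries": list(self.boundaries),
            "warning": self.warning,
        }


def _classify_scores(sample_id: str, x: np.ndarray, model: ReferenceModel,
                     boundaries: tuple[float, float]) -> ClassificationResult:
    theta_lo, theta_hi = boundaries
    if not (0 <= theta_lo < theta_hi <= 1):
        raise ValueError("boundaries must satisfy 0 <= lo < hi <= 1")
    d2 = {
        c: mahalanobis_sq(x, model.centroids[c], model.within_cov_inv)
        for c in model.class_order
    }
    pvals, flags = {}, {}
    for c, v in d2.items():
        p, o = outlier_p(v, model.k, model.outlier_alpha, model.outlier_tail)
        pvals[c], flags[c] = p, o
    overall = all(flags.values())

    ranked = sorted(model.class_order, key=lambda c: d2[c])
    stage1_pair = tuple(sorted(ranked[:2], key=lambda c: c.order))

    # Stage 2: among temporally adjacent pairs containing the closest
    # class, take the one with the smaller summed distance.  When the two
    # outer classes tie for closest, the pair sums break the tie; a full
    # tie falls back to the earlier (pre/receptive) pair, keeping the
    # receptive-adjacent in-range call.
    dmin = d2[ranked[0]]
    closest = [c for c in model.class_order if d2[c] <= dmin * (1 + 1e-12) + 1e-12]
    candidates = [p for p in ADJACENT_PAIRS if any(c in p for c in closest)]
    stage2_pair = min(candidates, key=lambda p: (d2[p[0]] + d2[p[1]],
                                                 ADJACENT_PAIRS.index(p)))

    a, b = stage2_pair  # temporally ordered: a earlier than b
    p_a, p_b = relative_probability(d2[a], d2[b])
    rel_prob = {a: p_a, b: p_b}
    if p_a >= theta_hi:
        final = a
    elif p_a <= theta_lo:
        final = b
    else:
        final = TRANSITION_BETWEEN[stage2_pair]
    warning = "outlier — interpret with caution" if overall else None
    return ClassificationResult(
        sample_id=sample_id, scores=x, d2=d2, outlier_p=pvals,
        is_outlier=flags, overall_outlier=overall, stage1_pair=stage1_pair,
        stage2_pair=stage2_pair, rel_prob=rel_prob, final_class=final,
        boundaries=boundaries, warning=warning,
    )


def classify(m: CountMatrix, model: ReferenceModel,
             boundaries: tuple[float, float] = (0.25, 0.75),
             ) -> list[ClassificationResult]:
    """Classify every sample of ``m`` with a fitted reference model."""
    scores, _ = model.transform(m)
    return [
        _classify_scores(sid, scores.loc[sid].to_numpy(), model, boundaries)
        for sid in scores.index
    ]


def classify_reference_only(m: CountMatrix, model: ReferenceModel
                            ) -> pd.Series:
    """Most probable of the three reference classes per sample (no
    transitionary calls) — the rule used inside cross-validation."""
    scores, _ = model.transform(m)
    out = {}
    for sid in scores.index:
        x = scores.loc[sid].to_numpy()
        d2 = {
            c: mahalanobis_sq(x, model.centroids[c], model.within_cov_inv)
            for c in model.class_order
        }
        out[sid] = min(model.class_order, key=lambda c: d2[c])
    return pd.Series(out, name="predicted")
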