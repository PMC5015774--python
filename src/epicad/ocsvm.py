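"""Per-voxel one-class SVM model banks with RBF kernel.

Each valid voxel gets its own one-class SVM trained on the cohort's
(junction_z, extension_z) feature vectors at that voxel.  The classifier is
the Schölkopf one-class formulation: separate the training examples from the
origin of the kernel feature space with maximum margin, allowing a
ν-controlled fraction of outliers.  The dual solved here is

    minimize   1/2 Σ_ij α_i α_j K(x_i, x_j)
    subject to 0 <= α_i <= 1/(ν n),  Σ_i α_i = 1,

with ``K(x, y) = exp(-||x - y||² / (2 σ²))``.  The model output is the
geometric signed distance ``(Σ_i α_i K(x_i, x) - ρ) / ||w||``; negative
distances mark the outlier side.

The solver is a deterministic SMO (maximal-violating-pair working set)
written for the tiny per-voxel problems (n <= a few dozen), batch-compiled
with numba so that hundreds of thousands of voxel models (bank training,
leave-one-out calibration, hyperparameter search) stay cheap.  Banks are
trained in voxel chunks; chunking is an execution detail and leaves the
result identical to sequential training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .features import FeatureVectorField

__all__ = [
    "OcsvmModel",
    "ModelBank",
    "ScoreMap",
    "rbf_kernel",
    "train_ocsvm",
    "signed_distance",
    "train_bank",
    "score_subject",
    "training_outlier_fraction",
    "estimate_loo_fpr",
    "select_hyperparameters",
    "default_nu_grid",
    "default_sigma_grid",
    "save_bank",
    "load_bank",
]

_SV_TOL = 1e-8
_BANK_FORMAT_VERSION = "epicad-bank-1"


def default_nu_grid() -> np.ndarray:
    """Eight log10-equally-spaced ν values spanning [0.01, 0.56]."""
    return np.logspace(np.log10(0.01), np.log10(0.56), 8)


def default_sigma_grid() -> np.ndarray:
    """Eight log2-equally-spaced σ values spanning [2^-4, 2^4]."""
    return np.logspace(-4.0, 4.0, 8, base=2.0)


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=False)
def _solve_dual(K, C, tol, max_iter):
    """SMO for: min 1/2 a'Ka  s.t.  0 <= a_i <= C, sum a = 1."""
    n = K.shape[0]
    alpha = np.zeros(n)
    acc = 0.0
    for i in range(n):  # feasible start: fill coordinates up to the bound
        take = min(C, 1.0 - acc)
        alpha[i] = take
        acc += take
        if acc >= 1.0 - 1e-15:
            break
    g = np.dot(K, alpha)
    eps_b = 1e-12 * max(C, 1.0)
    for _ in range(max_iter):
        g_min = 1e300
        g_max = -1e300
        i_up = -1
        i_lo = -1
        for i in range(n):
            if alpha[i] < C - eps_b and g[i] < g_min:
                g_min = g[i]
                i_up = i
            if alpha[i] > eps_b and g[i] > g_max:
                g_max = g[i]
                i_lo = i
        if i_up < 0 or i_lo < 0 or g_max - g_min < tol:
            break
        quad = K[i_up, i_up] + K[i_lo, i_lo] - 2.0 * K[i_up, i_lo]
        room = min(C - alpha[i_up], alpha[i_lo])
        if quad <= 1e-15:
            delta = room
        else:
            delta = min((g_max - g_min) / quad, room)
        alpha[i_up] += delta
        alpha[i_lo] -= delta
        for i in range(n):
            g[i] += delta * (K[i, i_up] - K[i, i_lo])
    return alpha


@njit(cache=False)
def _rho_wnorm(K, alpha, C):
    """Offset ρ (margin-SV average, KKT-midpoint fallback) and ||w||."""
    n = K.shape[0]
    g = np.dot(K, alpha)
    eps = 1e-7 * max(C, 1.0)
    s_free = 0.0
    n_free = 0
    g_bound_max = -1e300
    g_zero_min = 1e300
    for i in range(n):
        if alpha[i] > eps and alpha[i] < C - eps:
            s_free += g[i]
            n_free += 1
        elif alpha[i] >= C - eps:
            if g[i] > g_bound_max:
                g_bound_max = g[i]
        else:
            if g[i] < g_zero_min:
                g_zero_min = g[i]
    if n_free > 0:
        rho = s_free / n_free
    elif g_bound_max > -1e300 and g_zero_min < 1e300:
        rho = 0.5 * (g_bound_max + g_zero_min)
    elif g_bound_max > -1e300:
        rho = g_bound_max
    else:
        rho = g_zero_min
    wsq = 0.0
    for i in range(n):
        wsq += alpha[i] * g[i]
    return rho, np.sqrt(wsq)


@njit(cache=False)
def _train_many(K_all, C, tol, max_iter):
    V, n, _ = K_all.shape
    alphas = np.empty((V, n))
    rhos = np.empty(V)
    wnorms = np.empty(V)
    for v in range(V):
        a = _solve_dual(K_all[v], C, tol, max_iter)
        rho, w = _rho_wnorm(K_all[v], a, C)
        alphas[v] = a
        rhos[v] = rho
        wnorms[v] = w
    return alphas, rhos, wnorms


@njit(cache=False)
def _loo_scores(K_all, nu, tol, max_iter):
    """Leave-one-out signed distances and support-vector counts.

    For every voxel and every held-out subject s, train on the remaining
    n - 1 subjects and return the normalized signed distance of subject s.
    """
    V, n, _ = K_all.shape
    m = n - 1
    C = 1.0 / (nu * m)
    scores = np.empty((n, V))
    sv_total = 0
    Ksub = np.empty((m, m))
    kvec = np.empty(m)
    for v in range(V):
        K = K_all[v]
        for s in range(n):
            r = 0
            for i in range(n):
                if i == s:
                    continue
                kvec[r] = K[i, s]
                c = 0
                for j in range(n):
                    if j == s:
                        continue
                    Ksub[r, c] = K[i, j]
                    c += 1
                r += 1
            a = _solve_dual(Ksub, C, tol, max_iter)
            rho, w = _rho_wnorm(Ksub, a, C)
            val = 0.0
            for i in range(m):
                val += a[i] * kvec[i]
                if a[i] > 1e-8:
                    sv_total += 1
            scores[s, v] = (val - rho) / w
    return scores, sv_total


@njit(cache=False)
def _loo_refit_scores(X, sd_floor, nu, sigma, tol, max_iter):
    """Fully held-out LOO scores from raw (unstandardized) feature maps.

    For each voxel and held-out subject s, the cohort mean/SD are re-estimated
    from the remaining n - 1 subjects before z-scoring.  Pairwise feature
    differences cancel the fold mean, so only the fold SDs enter the Gram
    matrix; the per-voxel pairwise squared differences are computed once.
    Returns (n, V) signed distances, NaN where a fold SD falls below the floor.
    """
    n, V, p = X.shape
    m = n - 1
    C = 1.0 / (nu * m)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    scores = np.full((n, V), np.nan)
    D0 = np.empty((n, n))
    D1 = np.empty((n, n))
    Ksub = np.empty((m, m))
    kvec = np.empty(m)
    for v in range(V):
        for i in range(n):
            D0[i, i] = 0.0
            D1[i, i] = 0.0
            for j in range(i + 1, n):
                d0 = X[i, v, 0] - X[j, v, 0]
                d1 = X[i, v, 1] - X[j, v, 1]
                D0[i, j] = d0 * d0
                D0[j, i] = D0[i, j]
                D1[i, j] = d1 * d1
                D1[j, i] = D1[i, j]
        for s in range(n):
            mu0 = 0.0
            mu1 = 0.0
            for i in range(n):
                if i == s:
                    continue
                mu0 += X[i, v, 0]
                mu1 += X[i, v, 1]
            mu0 /= m
            mu1 /= m
            var0 = 0.0
            var1 = 0.0
            for i in range(n):
                if i == s:
                    continue
                var0 += (X[i, v, 0] - mu0) ** 2
                var1 += (X[i, v, 1] - mu1) ** 2
            var0 /= m
            var1 /= m
            if var0 < sd_floor * sd_floor or var1 < sd_floor * sd_floor:
                continue
            r = 0
            for i in range(n):
                if i == s:
                    continue
                kvec[r] = np.exp(-(D0[i, s] / var0 + D1[i, s] / var1) * inv2s2)
                c = 0
                for j in range(n):
                    if j == s:
                        continue
                    Ksub[r, c] = np.exp(-(D0[i, j] / var0 + D1[i, j] / var1) * inv2s2)
                    c += 1
                r += 1
            a = _solve_dual(Ksub, C, tol, max_iter)
            rho, w = _rho_wnorm(Ksub, a, C)
            val = 0.0
            for i in range(m):
                val += a[i] * kvec[i]
            scores[s, v] = (val - rho) / w
    return scores


# ---------------------------------------------------------------------------
# public API

def rbf_kernel(x, y, sigma: float) -> float:
    """``exp(-||x - y||² / (2 σ²))``, in (0, 1]."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return float(np.exp(-np.sum((x - y) ** 2) / (2.0 * sigma**2)))


def _gram(X: np.ndarray, sigma: float) -> np.ndarray:
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * sigma**2))


def _check_hyper(nu: float, sigma: float) -> None:
    if not 0.0 < nu <= 1.0:
        raise ValueError("nu must be in (0, 1]")
    if not sigma > 0:
        raise ValueError("sigma must be positive")


@dataclass
class OcsvmModel:
    """A trained per-voxel one-class SVM in dual form.

    ``support_vectors`` and ``dual_coefficients`` implicitly represent the
    hyperplane normal ``w = Σ_i α_i φ(x_i)``; slack variables are optimizer
    internals and are not persisted.
    """

    support_vectors: np.ndarray   # (k, p)
    dual_coefficients: np.ndarray  # (k,)
    rho: float
    sigma: float
    nu: float
    w_norm: float
    n_train: int


def train_ocsvm(X: np.ndarray, nu: float, sigma: float,
                tol: float = 1e-10, max_iter: int = 200_000) -> OcsvmModel:
    """Train one one-class SVM on an (n, p) training matrix."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("training matrix must be (n >= 2, p)")
    _check_hyper(nu, sigma)
    n = X.shape[0]
    C = 1.0 / (nu * n)
    K = _gram(X, sigma)
    alpha = _solve_dual(K, C, tol, max_iter)
    rho, w_norm = _rho_wnorm(K, alpha, C)
    sv = alpha > _SV_TOL
    return OcsvmModel(
        support_vectors=X[sv].copy(),
        dual_coefficients=alpha[sv].copy(),
        rho=float(rho),
        sigma=float(sigma),
        nu=float(nu),
        w_norm=float(w_norm),
        n_train=n,
    )


def signed_distance(model: OcsvmModel, x) -> float | np.ndarray:
    """Geometric signed distance of point(s) ``x`` to the model hyperplane.

    ``(Σ_i α_i K(x_i, x) - ρ) / ||w||``; negative values mark the outlier side.
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    pts = np.atleast_2d(x)
    d2 = ((model.support_vectors[None, :, :] - pts[:, None, :]) ** 2).sum(-1)
    k = np.exp(-d2 / (2.0 * model.sigma**2))
    vals = (k @ model.dual_coefficients - model.rho) / model.w_norm
    return float(vals[0]) if single else vals


@dataclass
class ScoreMap:
    """Per-voxel signed distances; excluded voxels hold the background value."""

    data: np.ndarray
    mask: np.ndarray
    background: float = np.nan

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise ValueError("score/mask shape mismatch")
        if not np.isfinite(self.data[self.mask]).all():
            raise ValueError("non-finite scores on the valid mask")

    @property
    def scores(self) -> np.ndarray:
        """Scores of the valid voxels, flat C-order."""
        return self.data[self.mask]


@dataclass
class ModelBank:
    """One one-class SVM per valid voxel, sharing (ν, σ) across voxels."""

    features: np.ndarray  # (n, V, p) training vectors
    alphas: np.ndarray    # (V, n)
    rhos: np.ndarray      # (V,)
    w_norms: np.ndarray   # (V,)
    mask: np.ndarray      # 3D bool, V valid voxels
    nu: float
    sigma: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_models(self) -> int:
        return self.alphas.shape[0]

    @property
    def n_train(self) -> int:
        return self.features.shape[0]

    def model_at(self, flat_index: int) -> OcsvmModel:
        """Materialize the per-voxel model at a flat valid-voxel index."""
        a = self.alphas[flat_index]
        sv = a > _SV_TOL
        return OcsvmModel(
            support_vectors=self.features[sv, flat_index, :].copy(),
            dual_coefficients=a[sv].copy(),
            rho=float(self.rhos[flat_index]),
            sigma=self.sigma, nu=self.nu,
            w_norm=float(self.w_norms[flat_index]),
            n_train=self.n_train,
        )


def _stack_fields(cohort_features: list[FeatureVectorField]) -> tuple[np.ndarray, np.ndarray]:
    if len(cohort_features) < 2:
        raise ValueError("need at least 2 subjects")
    mask = cohort_features[0].mask
    for f in cohort_features[1:]:
        if f.mask.shape != mask.shape or not (f.mask == mask).all():
            raise ValueError("feature fields do not share a common valid mask")
    F = np.stack([f.values for f in cohort_features])  # (n, V, p)
    return F, mask


def _gram_chunk(F: np.ndarray, sigma: float) -> np.ndarray:
    # F: (n, v, p) -> per-voxel Gram (v, n, n)
    d2 = ((F[:, None, :, :] - F[None, :, :, :]) ** 2).sum(-1)  # (n, n, v)
    return np.ascontiguousarray(np.exp(-d2 / (2.0 * sigma**2)).transpose(2, 0, 1))


def train_bank(cohort_features: list[FeatureVectorField], nu: float, sigma: float,
               chunk_size: int = 4096, tol: float = 1e-10,
               provenance: dict | None = None) -> ModelBank:
    """Train one one-class SVM per valid voxel over the cohort."""
    _check_hyper(nu, sigma)
    F, mask = _stack_fields(cohort_features)
    n, V, _ = F.shape
    C = 1.0 / (nu * n)
    alphas = np.empty((V, n))
    rhos = np.empty(V)
    wnorms = np.empty(V)
    for start in range(0, V, int(chunk_size)):
        sl = slice(start, min(start + int(chunk_size), V))
        K_all = _gram_chunk(F[:, sl, :], sigma)
        a, r, w = _train_many(K_all, C, tol, 200_000)
        alphas[sl] = a
        rhos[sl] = r
        wnorms[sl] = w
    return ModelBank(features=F, alphas=alphas, rhos=rhos, w_norms=wnorms,
                     mask=mask.copy(), nu=float(nu), sigma=float(sigma),
                     provenance=dict(provenance or {}))


def score_subject(bank: ModelBank, features: FeatureVectorField) -> ScoreMap:
    """Signed-distance map of a test subject under a trained bank."""
    if (features.mask.shape != bank.mask.shape
            or not (features.mask == bank.mask).all()):
        raise ValueError("feature field mask does not match the bank mask")
    d2 = ((bank.features - features.values[None, :, :]) ** 2).sum(-1)  # (n, V)
    k = np.exp(-d2 / (2.0 * bank.sigma**2))
    vals = (np.einsum("vn,nv->v", bank.alphas, k) - bank.rhos) / bank.w_norms
    data = np.full(bank.mask.shape, np.nan)
    data[bank.mask] = vals
    return ScoreMap(data=data, mask=bank.mask.copy())


def training_outlier_fraction(bank: ModelBank,
                              cohort_features: list[FeatureVectorField],
                              tol: float = 1e-8) -> float:
    """Mean fraction of training subjects with negative signed distance.

    Distances within ``tol`` of zero (margin support vectors up to solver
    tolerance) are not counted as outliers.
    """
    fracs = [np.mean(score_subject(bank, f).scores < -tol) for f in cohort_features]
    return float(np.mean(fracs))


def _sample_voxels(V: int, n_voxels: int, seed: int) -> np.ndarray:
    if n_voxels > V:
        raise ValueError("n_voxels exceeds the valid voxel count")
    rng = np.random.default_rng(int(seed))
    return np.sort(rng.choice(V, size=int(n_voxels), replace=False))


def _loo_stats(F: np.ndarray, nu: float, sigma: float,
               tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """LOO signed-distance matrix (n, V) and mean SV count per model."""
    n, V, _ = F.shape
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    scores = np.empty((n, V))
    sv_total = 0
    for start in range(0, V, 4096):
        sl = slice(start, min(start + 4096, V))
        K_all = _gram_chunk(F[:, sl, :], sigma)
        s, sv = _loo_scores(K_all, nu, tol, 200_000)
        scores[:, sl] = s
        sv_total += sv
    return scores, sv_total / (n * V)


def estimate_loo_fpr(cohort_features: list[FeatureVectorField], nu: float,
                     sigma: float, n_voxels: int = 4000, seed: int = 0) -> float:
    """Leave-one-out false-positive rate over randomly sampled voxels.

    For each sampled voxel and each held-out subject, a model is trained on
    the remaining subjects; the FPR is the fraction of held-out predictions
    with negative signed distance.
    """
    _check_hyper(nu, sigma)
    F, _ = _stack_fields(cohort_features)
    idx = _sample_voxels(F.shape[1], n_voxels, seed)
    scores, _ = _loo_stats(F[:, idx, :], nu, sigma)
    return float(np.mean(scores < 0.0))


def select_hyperparameters(cohort_features: list[FeatureVectorField],
                           nu_grid=None, sigma_grid=None,
                           n_voxels: int = 4000, seed: int = 0,
                           return_table: bool = False):
    """Grid search minimizing the leave-one-out FPR over sampled voxels.

    Ties are broken towards the least complex model: smallest mean number of
    support vectors, then smallest σ, then smallest ν.
    """
    nu_grid = default_nu_grid() if nu_grid is None else np.asarray(nu_grid, float)
    sigma_grid = (default_sigma_grid() if sigma_grid is None
                  else np.asarray(sigma_grid, float))
    if nu_grid.size == 0 or sigma_grid.size == 0:
        raise ValueError("empty hyperparameter grid")
    F, _ = _stack_fields(cohort_features)
    idx = _sample_voxels(F.shape[1], n_voxels, seed)
    Fs = F[:, idx, :]
    table = []
    for sigma in sigma_grid:
        for nu in nu_grid:
            scores, mean_sv = _loo_stats(Fs, float(nu), float(sigma))
            fpr = float(np.mean(scores < 0.0))
            table.append({"nu": float(nu), "sigma": float(sigma),
                          "loo_fpr": fpr, "mean_sv": float(mean_sv)})
    best = min(table, key=lambda r: (r["loo_fpr"], r["mean_sv"], r["sigma"], r["nu"]))
    if return_table:
        return (best["nu"], best["sigma"]), table
    return best["nu"], best["sigma"]


def save_bank(bank: ModelBank, path: str) -> None:
    """Serialize a bank to a single .npz archive with a format version tag."""
    np.savez_compressed(
        path, format=np.array(_BANK_FORMAT_VERSION), features=bank.features,
        alphas=bank.alphas, rhos=bank.rhos, w_norms=bank.w_norms,
        mask=bank.mask, nu=np.array(bank.nu), sigma=np.array(bank.sigma),
        provenance=np.array(repr(bank.provenance)),
    )


def load_bank(path: str) -> ModelBank:
    with np.load(path, allow_pickle=False) as z:
        if str(z["format"]) != _BANK_FORMAT_VERSION:
            raise ValueError(f"unsupported bank format: {z['format']}")
        import ast

        return ModelBank(
            features=z["features"], alphas=z["alphas"], rhos=z["rhos"],
            w_norms=z["w_norms"], mask=z["mask"].astype(bool),
            nu=float(z["nu"]), sigma=float(z["sigma"]),
            provenance=ast.literal_eval(str(z["provenance"])),
        )
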