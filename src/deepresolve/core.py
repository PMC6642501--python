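"""Gradient ascent in feature-map space and ensemble channel-importance summaries.

For a chosen class c the engine maximizes the regularized pre-sigmoid score

    H_c = argmax_H  S_c(H) - lambda * ||H||_2^2

over a free-valued (K, W) intermediate feature map H, starting from small
normal random initializations. The optimum is a *feature importance map*
(FIM); its per-channel spatial average is a *feature importance vector*
(FIV). Because the learned function is multimodal, the ascent is repeated T
times; trials are weighted by their final class score (offset so weights are
nonnegative), and the weighted variance of each channel's FIV across trials
is its *inconsistency level* (IL). Channels whose contribution flips between
modes — e.g. partners in an XOR — show high IL. A 1-3 component Gaussian
mixture on the IL scores (BIC-selected) separates additive/unimportant
channels from non-additive ones, and an *overall feature importance vector*
(OFIV) summarizes the ensemble per channel, averaging only positive trials
for non-additive channels of inconsistent sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.mixture import GaussianMixture

from .networks import ConvNet, FeatureSpaceHandle, feature_space

CATEGORY_ADDITIVE = "additive_or_unimportant"
CATEGORY_NONADD_CONSISTENT = "nonadditive_consistent"
CATEGORY_NONADD_INCONSISTENT = "nonadditive_inconsistent"


@dataclass(frozen=True)
class AscentConfig:
    """Hyperparameters of the regularized gradient ascent.

    ``lam`` is the L2 coefficient of the objective (explored range in
    practice: 0.3-2.8); the learning rate follows
    ``lr0 * max((step - start_decay)**(-alpha), min_lr)`` after
    ``start_decay`` steps and stays at ``lr0`` before that. ``T`` trials
    with N(0, init_std^2) initializations form the ensemble; ``init_std``
    must be large enough that different trials start in different linear
    regions of the ReLU network (different modes of the score surface) —
    with a near-zero start every trial follows the same trajectory and the
    ensemble collapses to one mode.
    """

    lam: float = 1.0
    lr0: float = 0.1
    start_decay: int = 50
    alpha: float = 0.5
    min_lr: float = 0.01
    n_steps: int = 200
    T: int = 10
    init_std: float = 0.5

    def __post_init__(self) -> None:
        if self.lam < 0 or self.lr0 <= 0 or self.n_steps < 1 or self.T < 1:
            raise ValueError("invalid ascent configuration")


def lr_at(step: int, cfg: AscentConfig) -> float:
    """Decayed learning rate at *step* (0-based); constant lr0 pre-decay."""
    if step <= cfg.start_decay:
        return cfg.lr0
    return cfg.lr0 * max((step - cfg.start_decay) ** (-cfg.alpha), cfg.min_lr)


@dataclass
class FeatureImportanceMap:
    """One gradient-ascent optimum: (K, W) map plus its final class score."""

    values: np.ndarray
    class_id: int
    final_score: float
    seed: int


def ascend(handle: FeatureSpaceHandle, c: int, cfg: AscentConfig,
           seed: int = 0) -> FeatureImportanceMap:
    """Run one regularized gradient-ascent trial for class *c*.

    The objective S_c(H) - lam*||H||^2 is monitored; a warning is emitted if
    it decreases on more than 5% of steps (learning rate too large for this
    landscape).
    """
    if c >= handle.n_outputs:
        raise ValueError(f"class {c} out of range (model has {handle.n_outputs})")
    rng = np.random.default_rng(seed)
    H = rng.normal(0.0, cfg.init_std, size=(handle.K, handle.W))
    obj_prev = handle.score(H, c) - cfg.lam * float(np.sum(H * H))
    n_decreases = 0
    for step in range(cfg.n_steps):
        g = handle.grad(H, c) - 2.0 * cfg.lam * H
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"non-finite gradient at step {step} of trial seed={seed}")
        H = H + lr_at(step, cfg) * g
        obj = handle.score(H, c) - cfg.lam * float(np.sum(H * H))
        if obj < obj_prev - 1e-12:
            n_decreases += 1
        obj_prev = obj
    if n_decreases > 0.05 * cfg.n_steps:
        warnings.warn(
            f"objective decreased on {n_decreases}/{cfg.n_steps} ascent steps "
            f"(class {c}, seed {seed}); consider a smaller lr0", stacklevel=2)
    return FeatureImportanceMap(values=H, class_id=c,
                                final_score=handle.score(H, c), seed=seed)


def fim_to_fiv(fim: FeatureImportanceMap | np.ndarray) -> np.ndarray:
    """Spatial average of a (K, W) feature importance map -> length-K FIV."""
    values = fim.values if isinstance(fim, FeatureImportanceMap) else np.asarray(fim)
    return values.mean(axis=1)


def trial_weights(scores: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Nonnegative trial weights: scores shifted by their minimum, plus eps.

    The worst trial keeps an infinitesimal weight so weighted statistics stay
    defined when T=1 or all scores tie.
    """
    scores = np.asarray(scores, dtype=float)
    return scores - scores.min() + eps


@dataclass
class FIVEnsemble:
    """T feature-importance vectors for one class with trial scores/weights."""

    fivs: np.ndarray             # (T, K)
    scores: np.ndarray           # (T,)
    weights: np.ndarray          # (T,) nonnegative
    class_id: int = 0
    fims: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("weights must be nonnegative with a positive sum")

    @property
    def T(self) -> int:
        return self.fivs.shape[0]

    @property
    def K(self) -> int:
        return self.fivs.shape[1]

    def weighted_mean(self) -> np.ndarray:
        w = self.weights / self.weights.sum()
        return w @ self.fivs


def run_trials(handle: FeatureSpaceHandle, c: int, cfg: AscentConfig,
               seed: int = 0) -> FIVEnsemble:
    """T gradient-ascent trials for class *c* from distinct seeded inits."""
    trial_seeds = np.random.SeedSequence(seed).generate_state(cfg.T) % (2 ** 31)
    fims = [ascend(handle, c, cfg, seed=int(s)) for s in trial_seeds]
    fivs = np.stack([fim_to_fiv(f) for f in fims])
    scores = np.array([f.final_score for f in fims])
    return FIVEnsemble(fivs=fivs, scores=scores,
                       weights=trial_weights(scores), class_id=c, fims=fims)


def inconsistency_level(ensemble: FIVEnsemble) -> np.ndarray:
    """Score-weighted variance of each channel's FIV across trials (IL)."""
    if ensemble.T < 2:
        raise ValueError("inconsistency level needs at least 2 trials")
    w = ensemble.weights / ensemble.weights.sum()
    mu = w @ ensemble.fivs
    return w @ (ensemble.fivs - mu) ** 2


@dataclass
class GMMResult:
    """BIC-selected univariate Gaussian mixture over IL scores."""

    n_components: int
    means: np.ndarray
    variances: np.ndarray
    mixing: np.ndarray
    assignments: np.ndarray      # per-channel component index
    bic: dict[int, float]

    @property
    def lowest_mean_component(self) -> int:
        return int(np.argmin(self.means))


def fit_il_gmm(il: np.ndarray, seed: int = 0, max_components: int = 3,
               n_init: int = 20, reg_covar: float | None = None,
               noise_scale: float | None = None,
               noise_tol: float = 1e-3) -> GMMResult:
    """Fit 1..max_components univariate mixtures to IL; keep the BIC minimizer.

    The covariance floor defaults to 1e-6 times the variance of the IL
    values: IL spans orders of magnitude, and an absolute floor larger than
    the within-cluster variance of the near-zero cluster would bias BIC
    against resolving it.

    Two degenerate cases short-circuit to a single component: all IL
    identical, and — when ``noise_scale`` (the ensemble's mean squared FIV,
    the natural unit of IL) is supplied — IL values that are uniformly
    negligible, ``max(IL) < noise_tol * noise_scale``. The second guard
    matters because trials that all converge to one optimum leave only
    convergence noise in IL, and a scale-invariant mixture fit would
    happily resolve "clusters" inside that noise.
    """
    il = np.asarray(il, dtype=float)
    if il.size < 1:
        raise ValueError("need at least one IL value")
    max_components = min(max_components, il.size)
    x = il.reshape(-1, 1)
    degenerate = np.ptp(il) == 0 or (
        noise_scale is not None and noise_scale > 0
        and il.max() < noise_tol * noise_scale)
    if degenerate:
        return GMMResult(1, means=np.array([il.mean()]),
                         variances=np.array([float(il.var())]),
                         mixing=np.array([1.0]),
                         assignments=np.zeros(il.size, dtype=int),
                         bic={1: float("nan")})
    if reg_covar is None:
        reg_covar = 1e-6 * float(np.var(il))
    bics: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for n in range(1, max_components + 1):
        gm = GaussianMixture(n_components=n, n_init=n_init, reg_covar=reg_covar,
                             random_state=seed, covariance_type="full")
        gm.fit(x)
        bics[n] = float(gm.bic(x))
        fits[n] = gm
    best = min(bics, key=bics.get)
    gm = fits[best]
    return GMMResult(
        n_components=best,
        means=gm.means_.ravel(),
        variances=gm.covariances_.ravel(),
        mixing=gm.weights_.ravel(),
        assignments=gm.predict(x),
        bic=bics,
    )


def categorize(ensemble: FIVEnsemble, gmm: GMMResult,
               weight_frac: float = 0.01) -> list[str]:
    """Per-channel category from IL mixture component and FIV sign pattern.

    Channels assigned to the lowest-mean IL component are additive or
    unimportant. Remaining channels are non-additive, split by whether all
    trials carrying more than *weight_frac* of the total weight agree in FIV
    sign.
    """
    low = gmm.lowest_mean_component
    significant = ensemble.weights > weight_frac * ensemble.weights.sum()
    if not np.any(significant):
        significant = ensemble.weights == ensemble.weights.max()
    cats = []
    for k in range(ensemble.K):
        if gmm.assignments[k] == low:
            cats.append(CATEGORY_ADDITIVE)
            continue
        phis = ensemble.fivs[significant, k]
        consistent = bool(np.all(phis >= 0) or np.all(phis <= 0))
        cats.append(CATEGORY_NONADD_CONSISTENT if consistent
                    else CATEGORY_NONADD_INCONSISTENT)
    return cats


@dataclass
class OFIVResult:
    """Overall per-channel importance for one class."""

    ofiv: np.ndarray
    il: np.ndarray
    category: list[str]
    gmm: GMMResult
    ensemble: FIVEnsemble

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": np.arange(self.ofiv.size),
            "ofiv": self.ofiv,
            "il": self.il,
            "category": self.category,
            "gmm_component": self.gmm.assignments,
        })

    def nonadditive_channels(self) -> np.ndarray:
        return np.flatnonzero([c != CATEGORY_ADDITIVE for c in self.category])


def compute_ofiv(ensemble: FIVEnsemble, categories: list[str],
                 il: np.ndarray | None = None,
                 gmm: GMMResult | None = None) -> OFIVResult:
    """Weighted-average OFIV; inconsistent channels average positive trials only."""
    w = ensemble.weights
    ofiv = np.empty(ensemble.K)
    base = (w / w.sum()) @ ensemble.fivs
    for k, cat in enumerate(categories):
        if cat == CATEGORY_NONADD_INCONSISTENT:
            pos = ensemble.fivs[:, k] > 0
            ofiv[k] = (w[pos] @ ensemble.fivs[pos, k] / w[pos].sum()
                       if np.any(pos) else 0.0)
        else:
            ofiv[k] = base[k]
    if il is None:
        il = (inconsistency_level(ensemble) if ensemble.T >= 2
              else np.zeros(ensemble.K))
    if gmm is None:
        gmm = fit_il_gmm(il)
    return OFIVResult(ofiv=ofiv, il=np.asarray(il), category=list(categories),
                      gmm=gmm, ensemble=ensemble)


def analyze_class(handle: FeatureSpaceHandle, c: int, cfg: AscentConfig,
                  seed: int = 0) -> OFIVResult:
    """Full per-class pipeline: trials -> IL -> GMM -> categories -> OFIV."""
    ensemble = run_trials(handle, c, cfg, seed=seed)
    if cfg.T >= 2:
        il = inconsistency_level(ensemble)
    else:
        il = np.zeros(ensemble.K)
    gmm = fit_il_gmm(il, seed=seed,
                     noise_scale=float(np.mean(ensemble.fivs ** 2)))
    cats = categorize(ensemble, gmm)
    return compute_ofiv(ensemble, cats, il=il, gmm=gmm)


def calibrate_lambda(handle: FeatureSpaceHandle, c: int,
                     sample_inputs: np.ndarray,
                     candidates: list[float],
                     cfg: AscentConfig | None = None,
                     seed: int = 0) -> float:
    """Pick the candidate L2 coefficient whose optimum ||H|| best matches data.

    The reference scale is the L2 norm of the mean pooled feature map over
    *sample_inputs*; for each candidate lambda one ascent trial is run and
    the lambda minimizing |  ||H_c|| - ||mean activation||  | is returned.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate lambda values")
    if sample_inputs.shape[0] == 0:
        raise ValueError("sample_inputs must be non-empty")
    cfg = cfg or AscentConfig()
    ref = float(np.linalg.norm(handle.activation_maps(sample_inputs).mean(axis=0)))
    gaps = []
    for lam in candidates:
        fim = ascend(handle, c, replace(cfg, lam=float(lam)), seed=seed)
        gaps.append(abs(float(np.linalg.norm(fim.values)) - ref))
    return float(candidates[int(np.argmin(gaps))])


class DeepResolve:
    """Interpretation model over a trained network's intermediate feature space.

    Statsmodels-style entry point: construct from a trained :class:`ConvNet`
    and a layer name, then :meth:`fit` runs the stochastic exploration for
    each requested class and returns a :class:`DeepResolveResults`.
    """

    def __init__(self, model: ConvNet, layer: str = "post_pool",
                 config: AscentConfig | None = None):
        self.model = model
        self.handle = feature_space(model, layer)
        self.config = config or AscentConfig()

    def fit(self, classes: list[int] | None = None,
            seed: int = 0) -> "DeepResolveResults":
        classes = (list(range(self.handle.n_outputs))
                   if classes is None else list(classes))
        class_seeds = np.random.SeedSequence(seed).generate_state(
            len(classes)) % (2 ** 31)
        results = {
            c: analyze_class(self.handle, c, self.config, seed=int(s))
            for c, s in zip(classes, class_seeds)
        }
        return DeepResolveResults(self, results, seed=seed)


class DeepResolveResults:
    """Per-class OFIV/IL/category results with tabular summaries."""

    def __init__(self, parent: DeepResolve, per_class: dict[int, OFIVResult],
                 seed: int = 0):
        self.model = parent.model
        self.config = parent.config
        self.per_class = per_class
        self.seed = seed

    @property
    def classes(self) -> list[int]:
        return sorted(self.per_class)

    def ofiv_matrix(self) -> np.ndarray:
        """(C, K) stack of OFIVs in class order."""
        return np.stack([self.per_class[c].ofiv for c in self.classes])

    def summary(self) -> pd.DataFrame:
        frames = []
        for c in self.classes:
            df = self.per_class[c].to_frame()
            df.insert(0, "class", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def gmm_components(self) -> dict[int, int]:
        return {c: self.per_class[c].gmm.n_components for c in self.classes}

    def to_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


def ranking_stability(handle: FeatureSpaceHandle, c: int,
                      lambdas: list[float], cfg: AscentConfig | None = None,
                      seed: int = 0) -> float:
    """Minimum pairwise Spearman correlation of OFIV rankings across lambdas."""
    cfg = cfg or AscentConfig()
    ofivs = []
    for lam in lambdas:
        res = analyze_class(handle, c, replace(cfg, lam=float(lam)), seed=seed)
        ofivs.append(res.ofiv)
    rhos = [spearmanr(ofivs[i], ofivs[j]).statistic
            for i in range(len(ofivs)) for j in range(i + 1, len(ofivs))]
    return float(min(rhos))
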