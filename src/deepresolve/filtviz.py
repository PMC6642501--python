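"""Channel-to-sequence visualization: PWMs, MEME export, input-space ascent,
activation profiles.

Each convolutional channel of a one-conv-layer genomic network is a candidate
motif detector. Two routes turn a channel into a position weight matrix:

* normalize its raw filter weights column-by-column (cheap, weight-level);
* L2-regularized gradient ascent on a relaxed (real-valued) input restricted
  to the channel's receptive field, maximizing the channel activation, then
  threshold and column-normalize (activation-level; different initializations
  can land in different modes, e.g. a motif vs its reverse complement, and
  all modes are kept).

PWMs are exported in MEME minimal format so external motif-comparison tools
can consume them. Activation profiles summarize how channel activity splits
positive from negative examples, grouped by overall-importance rank quartile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .syndata import ALPHABET, one_hot


@dataclass
class PWM:
    """Column-stochastic 4xL base-preference matrix."""

    probs: np.ndarray
    name: str = "motif"
    source: str = "filter_weights"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("PWM must be 4 x L")
        if np.any(self.probs < 0):
            raise ValueError("PWM entries must be nonnegative")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=0))


def filter_to_pwm(weights: np.ndarray, name: str = "filter",
                  mode: str = "minshift") -> PWM:
    """Normalize raw 4xL filter weights into a PWM.

    ``minshift`` subtracts each column's minimum and divides by the shifted
    column sum (uniform column if that sum is 0); ``softmax`` exponentiates
    instead.
    """
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("filter weights must be finite")
    if mode == "minshift":
        shifted = w - w.min(axis=0, keepdims=True)
        sums = shifted.sum(axis=0, keepdims=True)
        probs = np.where(sums > 0, shifted / np.where(sums > 0, sums, 1.0), 0.25)
    elif mode == "softmax":
        e = np.exp(w - w.max(axis=0, keepdims=True))
        probs = e / e.sum(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return PWM(probs=probs, name=name, source="filter_weights")


def info_content(pwm: PWM) -> tuple[np.ndarray, float]:
    """Per-column information content in bits (2 - Shannon entropy) and total."""
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    bits = 2.0 + plogp.sum(axis=0)
    return bits, float(bits.sum())


def write_meme(pwms: list[PWM], path) -> None:
    """Write PWMs in MEME minimal motif format (alphabet ACGT)."""
    if not pwms:
        raise ValueError("no PWMs to write")
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            L = len(pwm)
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {L}\n")
            for col in pwm.probs.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PWM]:
    """Parse a MEME minimal motif file back into PWMs (round-trip reader)."""
    pwms: list[PWM] = []
    name, rows, expect = None, [], 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split(maxsplit=2)[1]
                rows, expect = [], 0
            elif line.startswith("letter-probability matrix"):
                expect = int(line.split("w=")[1].split()[0])
            elif expect and line and line[0] in "0123456789.":
                rows.append([float(v) for v in line.split()])
                if len(rows) == expect:
                    probs = np.array(rows).T
                    probs = probs / probs.sum(axis=0, keepdims=True)
                    pwms.append(PWM(probs=probs, name=name or "motif"))
                    expect = 0
    return pwms


def pattern_match_scores(filters: np.ndarray, pattern: str) -> np.ndarray:
    """Score each 4xF filter against an exact DNA pattern.

    The score is the maximum over alignments of the mean filter weight along
    the pattern's one-hot path, minus the column-mean baseline — high for a
    filter whose weights prefer the pattern's bases at consecutive positions.
    """
    pat = one_hot(pattern)                       # (4, m)
    m = pat.shape[1]
    K, _, F = filters.shape
    scores = np.full(K, -np.inf)
    centered = filters - filters.mean(axis=1, keepdims=True)
    for off in range(max(F - m + 1, 1)):
        if off + m > F:
            break
        seg = centered[:, :, off: off + m]       # (K, 4, m)
        scores = np.maximum(scores, np.einsum("kam,am->k", seg, pat) / m)
    return scores


def best_matching_channel(filters: np.ndarray, pattern: str) -> int:
    """Index of the filter best matching *pattern* (see pattern_match_scores)."""
    return int(np.argmax(pattern_match_scores(filters, pattern)))


def channel_input_ascent(model, channel: int, init_fragments: list[str],
                         lam: float = 0.01, steps: int = 200, lr: float = 0.1,
                         threshold_frac: float = 0.1) -> tuple[list[PWM], PWM]:
    """Maximize one channel's activation over its receptive field.

    For a single-conv model the receptive field is ``filter_len`` bp and the
    channel's activation at a position is linear in the input, so the ascent
    optimizes x (4 x F real-valued) for  w_k . x - lam * ||x||^2  starting
    from each one-hot *init_fragment*. Entries below ``threshold_frac`` of
    their column maximum are zeroed before column normalization. Returns the
    per-initialization PWMs (modes are kept separate) and their average.
    """
    filters = model.conv_filters()
    if not 0 <= channel < filters.shape[0]:
        raise ValueError(f"channel {channel} out of range")
    w = filters[channel].astype(float)           # (4, F)
    F = w.shape[1]
    pwms = []
    for i, frag in enumerate(init_fragments):
        if len(frag) != F:
            raise ValueError(f"init fragment must be {F} bp")
        x = one_hot(frag).astype(float)
        for _ in range(steps):
            x = x + lr * (w - 2.0 * lam * x)
        x = np.maximum(x, 0.0)
        colmax = x.max(axis=0, keepdims=True)
        x = np.where(x < threshold_frac * np.maximum(colmax, 1e-12), 0.0, x)
        sums = x.sum(axis=0, keepdims=True)
        probs = np.where(sums > 0, x / np.where(sums > 0, sums, 1.0), 0.25)
        pwms.append(PWM(probs=probs, name=f"ch{channel}_init{i}",
                        source="input_ascent"))
    mean_probs = np.mean([p.probs for p in pwms], axis=0)
    mean_probs = mean_probs / mean_probs.sum(axis=0, keepdims=True)
    avg = PWM(probs=mean_probs, name=f"ch{channel}_mean", source="input_ascent")
    return pwms, avg


def top_activating_fragments(model, channel: int, sequences: list[str],
                             n: int = 10) -> list[str]:
    """The *n* receptive-field fragments that maximize a channel's activation."""
    from .syndata import encode_batch
    X = encode_batch(sequences)
    A = model._conv_relu(X)                      # (N, P, K)
    act = A[:, :, channel]
    flat = np.argsort(act, axis=None)[::-1][:n]
    F = model.arch.filter_len
    out = []
    for idx in flat:
        i, pos = np.unravel_index(idx, act.shape)
        out.append(sequences[i][pos: pos + F])
    return out


@dataclass
class ActivationProfile:
    """Mean channel activations on positive/negative examples, normalized to [0,1],
    with channels grouped into quartiles by overall-importance rank."""

    positive: np.ndarray         # (K,)
    negative: np.ndarray         # (K,)
    groups: list[np.ndarray]     # channel indices, ascending OFIV rank


def activation_profile(model, data, ofiv: np.ndarray, class_id: int = 0,
                       n_groups: int = 4) -> ActivationProfile:
    """Per-channel mean activation on positive vs negative examples.

    Activations are mean pooled-feature-map values, min-max normalized over
    all (channel, sign) cells of this network. Channels are split into
    ``n_groups`` nearly equal groups by ascending OFIV rank.
    """
    X = data.one_hot_matrix()
    y = data.labels[:, class_id].astype(bool)
    maps = model.pooled_activations(X)           # (N, K, W)
    per_seq = maps.mean(axis=2)                  # (N, K)
    pos = per_seq[y].mean(axis=0)
    neg = per_seq[~y].mean(axis=0)
    lo = min(pos.min(), neg.min())
    hi = max(pos.max(), neg.max())
    scale = hi - lo if hi > lo else 1.0
    pos_n, neg_n = (pos - lo) / scale, (neg - lo) / scale
    K = per_seq.shape[1]
    if K < n_groups:
        warnings.warn(f"only {K} channels; using {K} groups", stacklevel=2)
        n_groups = K
    order = np.argsort(np.asarray(ofiv))         # ascending importance
    groups = [np.sort(chunk) for chunk in np.array_split(order, n_groups)]
    return ActivationProfile(positive=pos_n, negative=neg_n, groups=groups)


def plot_logo(pwm: PWM, ax=None):
    """Minimal information-content-scaled sequence logo (letters as text)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(0.5 * len(pwm), 2))
    bits, _ = info_content(pwm)
    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    for j in range(len(pwm)):
        heights = pwm.probs[:, j] * bits[j]
        order = np.argsort(heights)
        y = 0.0
        for i in order:
            h = heights[i]
            if h <= 0:
                continue
            base = ALPHABET[i]
            ax.text(j + 0.5, y + h / 2, base, ha="center", va="center",
                    fontsize=14, color=colors[base],
                    fontweight="bold")
            y += h
    ax.set_xlim(0, len(pwm))
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xticks(np.arange(len(pwm)) + 0.5,
                  [str(i + 1) for i in range(len(pwm))])
    return ax
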