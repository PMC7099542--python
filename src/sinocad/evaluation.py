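"""ROC/AUC evaluation and the synthetic experiment harness.

The harness mirrors the comparisons of interest — projection view count,
direct-cut vs interleave-cut channelization, and image vs sinogram vs
combined inputs — on synthetic patch data.  Each condition is run
several times with fresh seeds (fresh dataset, ROI-level split, training)
and reported as mean +/- std of the held-out AUC, with full seed
provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classifier import CNNClassifier, DualInputCNNClassifier, split_dataset
from .phantom import generate_patch_dataset
from .sinogram import RadonTransform, SinogramChannelizer


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) method.

    Ties receive average ranks; the result equals the probability that a
    random positive outscores a random negative (ties counted half).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ExperimentResult:
    """Aggregated AUC of one condition over repeated seeded runs."""

    condition: str
    per_run_auc: list[float]
    seeds: list[int]
    config: dict = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return len(self.per_run_auc)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_run_auc))

    @property
    def std_auc(self) -> float:
        if self.n_runs < 2:
            return 0.0
        return float(np.std(self.per_run_auc, ddof=1))

    def __str__(self) -> str:
        return f"{self.condition}: AUC {self.mean_auc:.4f} +/- {self.std_auc:.4f} (n={self.n_runs})"


@dataclass
class ConditionConfig:
    """One experimental condition of the harness.

    ``input_kind`` selects the representation fed to the classifier:
    ``image`` (40x40 patch), ``sinogram`` (single-channel bins x views),
    ``stack`` (bins x views/C x C channel stack) or ``combined``
    (stack + image into the dual-branch net).
    """

    input_kind: str = "stack"
    n_views: int = 640
    n_channels: int = 16
    scheme: str = "interleave"
    step: int = 1
    n_bins: int = 40
    n_pos: int = 50
    n_neg: int = 50
    n_eval_pos: int = 75            # extra held-out ROIs for scoring only
    n_eval_neg: int = 75
    patch_size: int = 40
    difficulty: float = 1.0
    coding: str = "size_texture"    # labels depend jointly on size and texture
    epochs: int = 25
    batch_size: int = 30
    learning_rate: float = 1e-4
    patience: int = 3
    min_delta: float = 1e-3

    @property
    def label(self) -> str:
        if self.input_kind == "image":
            return "image"
        if self.input_kind == "sinogram":
            return f"sinogram views={self.n_views}"
        if self.input_kind == "stack":
            return f"{self.scheme}-cut views={self.n_views} channels={self.n_channels}"
        return f"combined views={self.n_views} channels={self.n_channels}"


def _representations(patches, cond: ConditionConfig):
    """Build the classifier inputs for one dataset under a condition."""
    imgs = np.stack([p.pixels for p in patches])
    if cond.input_kind == "image":
        return imgs
    sinos = RadonTransform(n_bins=cond.n_bins, n_views=cond.n_views,
                           normalize=True).transform(imgs)
    if cond.input_kind == "sinogram":
        return sinos
    stacks = SinogramChannelizer(n_channels=cond.n_channels, scheme=cond.scheme,
                                 step=cond.step).transform(sinos)
    if cond.input_kind == "stack":
        return stacks
    if cond.input_kind == "combined":
        return (stacks, imgs)
    raise ValueError(f"unknown input_kind {cond.input_kind!r}")


def _generate_run_data(cond: ConditionConfig, seed: int):
    """Training pool (ROI-split 80/20) plus an extra evaluation pool.

    The held-out side of the split is augmented with freshly drawn ROIs
    that never touch training; synthetic data is unlimited, and the wider
    evaluation pool narrows the AUC measurement noise without changing
    the training protocol.
    """
    patches = generate_patch_dataset(cond.n_pos, cond.n_neg, cond.patch_size,
                                     seed=seed, difficulty=cond.difficulty,
                                     coding=cond.coding)
    train, test = split_dataset(patches, fraction=0.8, seed=seed)
    if cond.n_eval_pos > 0 and cond.n_eval_neg > 0:
        extra = generate_patch_dataset(cond.n_eval_pos, cond.n_eval_neg,
                                       cond.patch_size, seed=seed + 500_009,
                                       difficulty=cond.difficulty,
                                       coding=cond.coding)
        for p in extra:
            p.roi_id = "eval_" + p.roi_id
        test = test + extra
    return train, test


def run_single(cond: ConditionConfig, seed: int) -> float:
    """One run of a condition: generate, split at ROI level, train, score."""
    train, test = _generate_run_data(cond, seed)
    common = dict(epochs=cond.epochs, batch_size=cond.batch_size,
                  learning_rate=cond.learning_rate, patience=cond.patience,
                  min_delta=cond.min_delta,
                  random_state=seed)
    y_train = np.array([p.label for p in train])
    y_test = np.array([p.label for p in test])
    if cond.input_kind == "combined":
        xs_tr = _representations(train, cond)
        xs_te = _representations(test, cond)
        clf = DualInputCNNClassifier(**common).fit(xs_tr, y_train)
        scores = clf.decision_scores(xs_te)
    else:
        clf = CNNClassifier(**common).fit(_representations(train, cond), y_train)
        scores = clf.decision_scores(_representations(test, cond))
    return roc_auc(scores, y_test)


def run_condition(cond: ConditionConfig, n_runs: int = 5,
                  base_seed: int = 0) -> ExperimentResult:
    """Repeat a condition with fresh seeds and aggregate mean +/- std AUC."""
    if n_runs < 1:
        raise ValueError("n_runs must be positive")
    seeds = [int(base_seed + 1000 * r + 1) for r in range(n_runs)]
    aucs = []
    for r, s in enumerate(seeds):
        try:
            aucs.append(run_single(cond, s))
        except Exception as err:            # noqa: BLE001 - annotate run index
            raise RuntimeError(f"run {r} (seed {s}) of '{cond.label}' failed") from err
    return ExperimentResult(condition=cond.label, per_run_auc=aucs,
                            seeds=seeds, config=asdict(cond))


def compare_conditions(results: list[ExperimentResult]) -> pd.DataFrame:
    """Rank conditions by mean AUC with pairwise differences.

    Returns a DataFrame sorted by descending mean AUC; the difference and
    pooled std columns compare each row against the top-ranked condition.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 results to compare")
    rows = [{"condition": r.condition, "mean_auc": r.mean_auc,
             "std_auc": r.std_auc, "n_runs": r.n_runs} for r in results]
    df = pd.DataFrame(rows).sort_values("mean_auc", ascending=False).reset_index(drop=True)
    best = df.loc[0]
    df["diff_vs_best"] = best["mean_auc"] - df["mean_auc"]
    df["pooled_std_vs_best"] = np.sqrt((best["std_auc"] ** 2 + df["std_auc"] ** 2) / 2.0)
    return df


def results_table(results: list[ExperimentResult]) -> pd.DataFrame:
    """Long-form per-run table (condition, run, seed, auc)."""
    rows = []
    for res in results:
        for run, (seed, auc) in enumerate(zip(res.seeds, res.per_run_auc)):
            rows.append({"condition": res.condition, "run": run, "seed": seed, "auc": auc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# experiment suites
# ---------------------------------------------------------------------------

def _from_base_sinogram(base: np.ndarray, base_views: int, cond: ConditionConfig):
    """Derive a condition's projection input from a dense base sinogram.

    A V-view geometry's angles are an exact subset of the base geometry's
    when V divides the base view count, so subsampling the view axis
    reproduces the V-view projection; normalization happens after the
    subset, exactly as in the direct path.
    """
    if base_views % cond.n_views != 0:
        raise ValueError("base view count must be a multiple of the condition's")
    sub = base[:, :, :: base_views // cond.n_views]
    from .core import minmax_normalize
    sub = np.stack([minmax_normalize(s) for s in sub])
    if cond.input_kind == "sinogram":
        return sub
    return SinogramChannelizer(n_channels=cond.n_channels, scheme=cond.scheme,
                               step=cond.step).transform(sub)


def run_suite(conds: list[ConditionConfig], n_runs: int = 5,
              base_seed: int = 0) -> list[ExperimentResult]:
    """Run several conditions on shared per-run datasets.

    All conditions see identical data in each run: the labelled patch set
    and its ROI-level split are generated once per run seed, and one
    dense base sinogram serves every projection-based condition by exact
    angle subsetting.  This keeps the comparisons paired (differences
    between conditions are not confounded by dataset draws).
    """
    first = conds[0]
    if any((c.n_pos, c.n_neg, c.n_eval_pos, c.n_eval_neg, c.patch_size,
            c.difficulty, c.coding)
           != (first.n_pos, first.n_neg, first.n_eval_pos, first.n_eval_neg,
               first.patch_size, first.difficulty, first.coding)
           for c in conds):
        raise ValueError("suite conditions must share dataset parameters")
    need_proj = [c for c in conds if c.input_kind != "image"]
    if need_proj and len({c.n_bins for c in need_proj}) > 1:
        raise ValueError("suite conditions must share the detector bin count")
    base_views = 1
    for c in need_proj:
        base_views = int(base_views * c.n_views // np.gcd(base_views, c.n_views))
    seeds = [int(base_seed + 1000 * r + 1) for r in range(n_runs)]
    aucs: dict[int, list[float]] = {i: [] for i in range(len(conds))}
    for seed in seeds:
        train, test = _generate_run_data(first, seed)
        imgs = {"train": np.stack([p.pixels for p in train]),
                "test": np.stack([p.pixels for p in test])}
        ys = {"train": np.array([p.label for p in train]),
              "test": np.array([p.label for p in test])}
        sino = {}
        if need_proj:
            rt = RadonTransform(n_bins=need_proj[0].n_bins, n_views=base_views,
                                normalize=False)
            sino = {k: rt.transform(v) for k, v in imgs.items()}
        for i, cond in enumerate(conds):
            if cond.input_kind == "image":
                x_tr, x_te = imgs["train"], imgs["test"]
            else:
                x_tr = _from_base_sinogram(sino["train"], base_views, cond)
                x_te = _from_base_sinogram(sino["test"], base_views, cond)
                if cond.input_kind == "combined":
                    x_tr, x_te = (x_tr, imgs["train"]), (x_te, imgs["test"])
            common = dict(epochs=cond.epochs, batch_size=cond.batch_size,
                          learning_rate=cond.learning_rate, patience=cond.patience,
                  min_delta=cond.min_delta,
                          random_state=seed)
            if cond.input_kind == "combined":
                clf = DualInputCNNClassifier(**common).fit(x_tr, ys["train"])
            else:
                clf = CNNClassifier(**common).fit(x_tr, ys["train"])
            aucs[i].append(roc_auc(clf.decision_scores(x_te), ys["test"]))
    return [ExperimentResult(condition=c.label, per_run_auc=aucs[i], seeds=seeds,
                             config=asdict(c)) for i, c in enumerate(conds)]


def view_sweep_suite(views=(40, 160, 640), n_runs: int = 5, base_seed: int = 0,
                     **overrides) -> list[ExperimentResult]:
    """AUC as a function of projection view count.

    Each view count V is fed as an interleave-cut stack of V/40 channels
    of 40 views (V=40 is the single-channel case), so the network input
    stays bins x 40 x C while the angular sampling grows with V.
    """
    conds = [ConditionConfig(input_kind="stack", n_views=v,
                             n_channels=max(1, v // 40), scheme="interleave",
                             **overrides) for v in views]
    return run_suite(conds, n_runs=n_runs, base_seed=base_seed)


def cut_comparison_suite(n_views: int = 640, n_channels: int = 16, n_runs: int = 5,
                         base_seed: int = 0, **overrides) -> list[ExperimentResult]:
    """Direct-cut vs interleave-cut at a fixed view/channel configuration."""
    conds = [ConditionConfig(input_kind="stack", n_views=n_views,
                             n_channels=n_channels, scheme=scheme, **overrides)
             for scheme in ("direct", "interleave")]
    return run_suite(conds, n_runs=n_runs, base_seed=base_seed)


def domain_comparison_suite(n_views: int = 640, n_channels: int = 16, n_runs: int = 5,
                            base_seed: int = 0, **overrides) -> list[ExperimentResult]:
    """Image-only vs sinogram-only vs combined dual-branch input."""
    conds = [
        ConditionConfig(input_kind="image", **overrides),
        ConditionConfig(input_kind="stack", n_views=n_views, n_channels=n_channels,
                        scheme="interleave", **overrides),
        ConditionConfig(input_kind="combined", n_views=n_views, n_channels=n_channels,
                        scheme="interleave", **overrides),
    ]
    return run_suite(conds, n_runs=n_runs, base_seed=base_seed)


def plot_comparison(results: list[ExperimentResult], path: str) -> None:
    """Bar chart of condition AUCs (mean +/- std) saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.8 * len(results) + 2, 4))
    xs = np.arange(len(results))
    ax.bar(xs, [r.mean_auc for r in results],
           yerr=[r.std_auc for r in results], capsize=4)
    ax.set_xticks(xs)
    ax.set_xticklabels([r.condition for r in results], rotation=20, ha="right")
    ax.set_ylabel("AUC")
    ax.set_ylim(0.5, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
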