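"""Feature-selection scoring and the replication study harness.

A fitted sparse model "selects" a feature when its loading survives the
soft-thresholding in any extracted rank.  Against a simulated ground
truth the selection is scored by a pooled confusion matrix and the three
headline rates:

    TPR  = TP / (TP + FN)        (sensitivity)
    PPV  = TP / (TP + FP)        (precision)
    ACCU = (TP + TN) / total     (accuracy)

True-negative-based rates are uninformative here because the truly null
features vastly outnumber the signal ones.  The replication harness
repeats simulate/fit/score over independently seeded datasets and
reports mean +/- sd per method, mirroring how feature-selection
performance of sparse multiblock models is benchmarked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import BlockGraph, MultiblockData, default_genomic_graph
from .optimizer import FitOptions, LoadingSet, fit
from .simulation import SimConfig, SimTruth, simulate_dataset

__all__ = [
    "SelectionResult",
    "StudyResult",
    "select_features",
    "score_selection",
    "run_study",
    "METHODS",
]

#: Fitting configurations the study harness knows how to run.
METHODS = ("multida", "sgcca_mode")


@dataclass
class SelectionResult:
    """Pooled confusion counts and rates of one scored selection."""

    selected: list[np.ndarray]
    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    ppv: float
    accu: float
    undefined: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "TPR": self.tpr,
            "PPV": self.ppv,
            "ACCU": self.accu,
            "undefined": list(self.undefined),
        }


def select_features(
    loading_set: LoadingSet, threshold: float = 0.0
) -> list[np.ndarray]:
    """Binary selection masks per feature block (class block excluded).

    A feature is selected iff the absolute value of its loading exceeds
    ``threshold`` in at least one rank.  With the default threshold of
    zero this is exactly the set of coefficients that survived
    soft-thresholding.
    """
    n_feature_blocks = len(loading_set.feature_names) - 1
    if loading_set.n_ranks == 0:
        return [
            np.zeros(len(loading_set.feature_names[j]), dtype=int)
            for j in range(n_feature_blocks)
        ]
    masks = []
    for j in range(n_feature_blocks):
        stacked = loading_set.block_loadings(j)
        masks.append((np.abs(stacked) > threshold).any(axis=0).astype(int))
    return masks


def score_selection(
    selected: Sequence[np.ndarray],
    truth: SimTruth | Sequence[np.ndarray],
    blocks_evaluated: Sequence[int] | None = None,
) -> SelectionResult:
    """Confusion matrix and rates of a selection against ground truth.

    Counts are pooled over ``blocks_evaluated`` (default: all feature
    blocks, i.e. predictor blocks plus the response block).  A rate with
    a zero denominator is defined as 0 and flagged in ``undefined``.
    """
    masks = truth.masks if isinstance(truth, SimTruth) else list(truth)
    if blocks_evaluated is None:
        blocks_evaluated = range(len(selected))
    tp = fp = tn = fn = 0
    for j in blocks_evaluated:
        sel = np.asarray(selected[j]).astype(bool)
        tru = np.asarray(masks[j]).astype(bool)
        if sel.shape != tru.shape:
            raise ValueError(
                f"block {j}: selection length {sel.size} does not match "
                f"truth length {tru.size}"
            )
        tp += int(np.sum(sel & tru))
        fp += int(np.sum(sel & ~tru))
        fn += int(np.sum(~sel & tru))
        tn += int(np.sum(~sel & ~tru))
    undefined = []
    if tp + fn > 0:
        tpr = tp / (tp + fn)
    else:
        tpr, undefined = 0.0, undefined + ["TPR"]
    if tp + fp > 0:
        ppv = tp / (tp + fp)
    else:
        ppv, undefined = 0.0, undefined + ["PPV"]
    total = tp + fp + tn + fn
    if total > 0:
        accu = (tp + tn) / total
    else:
        accu, undefined = 0.0, undefined + ["ACCU"]
    return SelectionResult(
        selected=[np.asarray(s, dtype=int) for s in selected],
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        tpr=tpr,
        ppv=ppv,
        accu=accu,
        undefined=undefined,
    )


@dataclass
class StudyResult:
    """Replication-study output: per-replication records and a summary."""

    records: pd.DataFrame
    summary: pd.DataFrame
    n_replications: int
    failures: list[dict] = field(default_factory=list)

    def mean(self, method: str, metric: str) -> float:
        row = self.summary[
            (self.summary["method"] == method) & (self.summary["metric"] == metric)
        ]
        return float(row["mean"].iloc[0])


def _method_options(method: str, base: FitOptions, seed: int) -> FitOptions:
    opts = FitOptions.from_dict(base.to_dict())
    opts.seed = seed
    if method == "multida":
        opts.sgcca_mode = False
        opts.discriminant = True
    elif method == "sgcca_mode":
        opts.sgcca_mode = True
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return opts


def run_study(
    config: SimConfig | None = None,
    n_replications: int = 50,
    methods: Sequence[str] = ("multida",),
    master_seed: int = 0,
    *,
    fit_options: FitOptions | None = None,
    graph: BlockGraph | None = None,
    blocks_evaluated: Sequence[int] | None = None,
    progress: bool = False,
) -> StudyResult:
    """Repeat simulate / fit / score and aggregate the selection rates.

    Every replication draws a fresh dataset from a child stream of
    ``master_seed``, fits each requested method on the same dataset and
    scores the selected features against the ground-truth masks.  The
    summary reports mean, sample standard deviation and standard error
    of TPR / PPV / ACCU per method.  A failed replication is recorded in
    ``failures`` and excluded, with a warning.
    """
    config = config or SimConfig()
    base = fit_options or FitOptions()
    graph = graph or default_genomic_graph()
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")

    root = np.random.SeedSequence(master_seed)
    rows = []
    failures = []
    for rep, child in enumerate(root.spawn(n_replications)):
        data_seed, *fit_seeds = child.generate_state(1 + len(methods)) % (2**31)
        try:
            data, truth = simulate_dataset(config, np.random.SeedSequence(int(data_seed)))
            for method, fseed in zip(methods, fit_seeds):
                opts = _method_options(method, base, int(fseed))
                loading_set = fit(data, graph, opts)
                selected = select_features(loading_set)
                score = score_selection(selected, truth, blocks_evaluated)
                rows.append(
                    {
                        "replication": rep,
                        "method": method,
                        "TPR": score.tpr,
                        "PPV": score.ppv,
                        "ACCU": score.accu,
                        "TP": score.tp,
                        "FP": score.fp,
                        "TN": score.tn,
                        "FN": score.fn,
                        "n_ranks": loading_set.n_ranks,
                    }
                )
        except Exception as exc:  # noqa: BLE001 - a bad draw must not kill the study
            failures.append({"replication": rep, "error": repr(exc)})
            warnings.warn(f"replication {rep} failed and was excluded: {exc!r}")
        if progress:
            print(f"replication {rep + 1}/{n_replications} done", flush=True)

    records = pd.DataFrame(rows)
    summary_rows = []
    for method in methods:
        sub = records[records["method"] == method]
        for metric in ("TPR", "PPV", "ACCU"):
            vals = sub[metric].to_numpy()
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            summary_rows.append(
                {
                    "method": method,
                    "metric": metric,
                    "mean": float(np.mean(vals)) if len(vals) else float("nan"),
                    "sd": sd,
                    "se": sd / np.sqrt(len(vals)) if len(vals) > 1 else 0.0,
                    "n_reps": int(len(vals)),
                }
            )
    summary = pd.DataFrame(summary_rows)
    return StudyResult(
        records=records,
        summary=summary,
        n_replications=n_replications,
        failures=failures,
    )
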