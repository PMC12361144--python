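"""Evaluation: classification metrics, the late-fusion baseline and McNemar tests.

The late-fusion baseline averages the class-probability vectors of the
unimodal models available for an instance and takes the argmax; it is the
decision-level reference the learned fusion model must beat.  All headline
metrics are macro-averaged (computed per class and averaged uniformly), which
is insensitive to class frequencies and therefore comparable across modality
subsets of very different composition.  Paired model comparisons use
McNemar's test on the discordant correct/incorrect counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray


def confusion_counts(predictions: np.ndarray, labels: np.ndarray,
                     n_classes: int) -> ConfusionCounts:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    total = len(labels)
    tp = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros(n_classes, dtype=np.int64)
    fn = np.zeros(n_classes, dtype=np.int64)
    np.add.at(tp, labels[predictions == labels], 1)
    np.add.at(fp, predictions[predictions != labels], 1)
    np.add.at(fn, labels[predictions != labels], 1)
    tn = total - tp - fp - fn
    return ConfusionCounts(tp, tn, fp, fn)


def _macro(numer: np.ndarray, denom: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-class ratios with zero denominators mapped to 0 (counted)."""
    vals = np.zeros(len(numer))
    ok = denom > 0
    vals[ok] = numer[ok] / denom[ok]
    return vals, int((~ok).sum())


def f1_macro(predictions: np.ndarray, labels: np.ndarray, n_classes: int) -> float:
    """Mean over classes of the per-class F1 = 2PR/(P+R)."""
    cc = confusion_counts(predictions, labels, n_classes)
    prec, _ = _macro(cc.tp, cc.tp + cc.fp)
    rec, _ = _macro(cc.tp, cc.tp + cc.fn)
    f1, _ = _macro(2 * prec * rec, prec + rec)
    return float(f1.mean())


def top_n_correct(probs: np.ndarray, labels: np.ndarray, n: int) -> np.ndarray:
    """Per-instance flags: true class within the first n after a stable sort
    by (-probability, class index)."""
    order = np.lexsort((np.arange(probs.shape[1])[None, :].repeat(len(probs), 0),
                        -probs), axis=1)
    ranks = np.argsort(order, axis=1)
    return ranks[np.arange(len(labels)), labels] < n


def compute_metrics(probs: np.ndarray, labels: np.ndarray,
                    top_ns: tuple[int, ...] = (1, 5, 10)) -> dict:
    """Accuracy, macro precision/recall/F1 and top-N accuracies.

    Macro F1 is the arithmetic mean of per-class F1 scores (not the harmonic
    combination of macro precision and macro recall).  Classes with a zero
    denominator score 0 and are counted in ``undefined_precision_classes`` /
    ``undefined_recall_classes``.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("cannot compute metrics for zero instances")
    n_classes = probs.shape[1]
    predictions = np.argmax(probs, axis=1)
    cc = confusion_counts(predictions, labels, n_classes)
    prec, n_undef_p = _macro(cc.tp, cc.tp + cc.fp)
    rec, n_undef_r = _macro(cc.tp, cc.tp + cc.fn)
    f1, _ = _macro(2 * prec * rec, prec + rec)
    report = {
        "accuracy": float(cc.tp.sum() / len(labels)),
        "precision_macro": float(prec.mean()),
        "recall_macro": float(rec.mean()),
        "f1_macro": float(f1.mean()),
        "undefined_precision_classes": n_undef_p,
        "undefined_recall_classes": n_undef_r,
        "n_instances": len(labels),
    }
    for n in top_ns:
        report[f"top_{n}_accuracy"] = float(top_n_correct(probs, labels, n).mean())
    return report


# ---------------------------------------------------------------------------
# late-fusion baseline
# ---------------------------------------------------------------------------

def late_fusion_probs(model_probs: list[np.ndarray]) -> np.ndarray:
    """Average the available unimodal models' probability rows."""
    if not model_probs:
        raise ValueError("late fusion needs at least one available model")
    return np.mean(model_probs, axis=0)


def late_fusion_predict(model_probs: list[np.ndarray]) -> np.ndarray:
    """argmax_c mean_m p_m(c | x); argmax ties go to the lowest class index."""
    return np.argmax(late_fusion_probs(model_probs), axis=-1)


# ---------------------------------------------------------------------------
# McNemar's test
# ---------------------------------------------------------------------------

@dataclass
class McNemarResult:
    chi2: float
    p_value: float
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    degenerate: bool = False


def mcnemar_test(correct_a: np.ndarray, correct_b: np.ndarray,
                 exact: bool = False) -> McNemarResult:
    """Paired comparison of two classifiers from per-instance correctness flags.

    Continuity-corrected chi-square on the discordant pairs:
    chi2 = (|b - c| - 1)^2 / (b + c) with 1 degree of freedom; symmetric in
    its arguments.  ``exact=True`` uses the two-sided binomial test instead
    (preferable for small b + c).
    """
    correct_a = np.asarray(correct_a, dtype=bool)
    correct_b = np.asarray(correct_b, dtype=bool)
    if correct_a.shape != correct_b.shape:
        raise ValueError("flag vectors must have equal length")
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    if b + c == 0:
        return McNemarResult(0.0, 1.0, b, c, degenerate=True)
    if exact:
        p = float(stats.binomtest(min(b, c), b + c, 0.5).pvalue)
        chi2 = (abs(b - c) - 1) ** 2 / (b + c)
        return McNemarResult(float(chi2), p, b, c)
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(float(chi2), p, b, c)


# ---------------------------------------------------------------------------
# modality-subset evaluation
# ---------------------------------------------------------------------------

def evaluate_modality_subsets(labels: np.ndarray,
                              modality_sets: list[frozenset | set],
                              proposed_probs_fn,
                              unimodal_probs: dict[str, np.ndarray],
                              subsets: list[tuple[str, ...]],
                              n_classes: int) -> list[dict]:
    """Compare the fusion model and the late-fusion baseline per organ subset.

    For each subset, only records possessing *every* organ in the subset are
    evaluated.  The proposed model receives zeros (zero-image features) for
    organs outside the subset — ``proposed_probs_fn(indices, subset)`` must
    return its probabilities under that restriction — while the baseline
    averages only the unimodal models for organs in the subset.  Each row
    carries the subset, the number of qualifying predictions, both macro F1
    scores and the McNemar comparison.
    """
    labels = np.asarray(labels)
    rows = []
    for subset in subsets:
        subset = tuple(subset)
        idx = np.array([i for i, mods in enumerate(modality_sets)
                        if set(subset) <= set(mods)], dtype=int)
        row = {"subset": subset, "n_predictions": len(idx)}
        if len(idx) == 0:
            rows.append(row)
            continue
        probs_prop = proposed_probs_fn(idx, subset)
        pred_prop = np.argmax(probs_prop, axis=1)
        probs_base = late_fusion_probs([unimodal_probs[o][idx] for o in subset])
        pred_base = np.argmax(probs_base, axis=1)
        y = labels[idx]
        mc = mcnemar_test(pred_prop == y, pred_base == y)
        row.update({
            "f1_macro_proposed": f1_macro(pred_prop, y, n_classes),
            "f1_macro_baseline": f1_macro(pred_base, y, n_classes),
            "mcnemar_chi2": mc.chi2,
            "mcnemar_p": mc.p_value,
        })
        rows.append(row)
    return rows
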