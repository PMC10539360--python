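"""Mixed categorical/continuous association scoring and evaluation metrics.

One scalar association score on [0, 1] for any pair of variables, chosen by
their declared kinds: |Spearman rho| for continuous pairs, |Goodman-Kruskal
gamma| for ordinal pairs, Cramer's V for nominal pairs, and for a
categorical-continuous pair the class-rebalanced (SMOTE) logistic-regression
AU-ROC rescaled to [0, 1] as 2*|AUROC - 1/2|.

Also houses the evaluation metrics: adjusted balanced accuracy (mean over
classes of (sensitivity + specificity)/2), adjusted AU-PRC (chance-level
subtracted and rescaled), and "predictability" — the score of a k-NN model
under patient-grouped cross-validation (AU-ROC for classification,
|Spearman rho| for regression).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor, NearestNeighbors


@dataclass
class AssociationScore:
    method: str
    score: float
    p_value: float
    defined: bool = True


def goodman_kruskal_gamma(table: np.ndarray) -> float:
    """Gamma = (C - D) / (C + D) from a contingency table of ordered variables.

    C (D) counts concordant (discordant) pairs: cell pairs where both row and
    column order agree (disagree).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-D")
    r, c = t.shape
    concordant = discordant = 0.0
    for i in range(r):
        for j in range(c):
            concordant += t[i, j] * t[i + 1 :, j + 1 :].sum()
            discordant += t[i, j] * t[i + 1 :, :j].sum()
    if concordant + discordant == 0:
        raise ValueError("gamma undefined: no concordant or discordant pairs")
    return float((concordant - discordant) / (concordant + discordant))


def cramers_v(table: np.ndarray) -> tuple:
    """(Cramer's V, p) from a nominal contingency table."""
    t = np.asarray(table, dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    n = t.sum()
    k = min(t.shape) - 1
    if n == 0 or k == 0:
        raise ValueError("Cramer's V undefined")
    return float(np.sqrt(chi2 / (n * k))), float(p)


def smote_oversample(X: np.ndarray, y: np.ndarray, k: int = 5, rng=None):
    """Minority oversampling by convex combinations of within-class neighbors.

    Balances every class up to the majority count. Applied inside CV folds
    only, never before splitting.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    xs, ys = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = n_max - cnt
        if need == 0:
            continue
        Xc = X[y == cls]
        if len(Xc) == 1:
            synth = np.repeat(Xc, need, axis=0)
        else:
            nn = NearestNeighbors(n_neighbors=min(k + 1, len(Xc))).fit(Xc)
            _, idx = nn.kneighbors(Xc)
            base = rng.integers(0, len(Xc), size=need)
            neigh = idx[base, rng.integers(1, idx.shape[1], size=need)]
            u = rng.random((need, 1))
            synth = Xc[base] + u * (Xc[neigh] - Xc[base])
        xs.append(synth)
        ys.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(xs), np.concatenate(ys)


def _logistic_auroc(cont: np.ndarray, cat: np.ndarray, rng) -> tuple:
    """Class-rebalanced logistic regression AU-ROC of continuous vs categorical."""
    X = np.asarray(cont, dtype=float).reshape(-1, 1)
    codes, _ = pd.factorize(cat)
    classes, counts = np.unique(codes, return_counts=True)
    n_splits = int(min(3, counts.min()))
    if n_splits < 2:
        # too few per class to cross-validate; fit on the full data
        Xb, yb = smote_oversample(X, codes, rng=rng)
        clf = LogisticRegression(max_iter=1000).fit(Xb, yb)
        prob = clf.predict_proba(X)
        oof_prob, oof_y = prob, codes
    else:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=0)
        oof_prob = np.zeros((len(codes), len(classes)))
        for tr, te in skf.split(X, codes):
            Xb, yb = smote_oversample(X[tr], codes[tr], rng=rng)
            clf = LogisticRegression(max_iter=1000).fit(Xb, yb)
            prob = clf.predict_proba(X[te])
            for ci, cls in enumerate(clf.classes_):
                oof_prob[te, cls] = prob[:, ci]
        oof_y = codes
    if len(classes) == 2:
        auc = roc_auc_score(oof_y, oof_prob[:, 1])
    else:
        auc = roc_auc_score(oof_y, oof_prob, multi_class="ovr", average="micro")
    return float(auc), codes


def mixed_association(a, b, kind_a: str, kind_b: str, rng=None) -> AssociationScore:
    """Association score on [0, 1] for a pair of variables of declared kinds."""
    a = pd.Series(a)
    b = pd.Series(b)
    keep = a.notna() & b.notna()
    a, b = a[keep], b[keep]
    if len(a) < 5:
        raise ValueError("need at least 5 paired observations")
    if a.nunique() < 2 or b.nunique() < 2:
        return AssociationScore(method="undefined", score=float("nan"),
                                p_value=float("nan"), defined=False)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    continuous = {"continuous"}
    if kind_a in continuous and kind_b in continuous:
        rho, p = stats.spearmanr(a.astype(float), b.astype(float))
        return AssociationScore("spearman", abs(float(rho)), float(p))
    if kind_a == "ordinal" and kind_b == "ordinal":
        table = pd.crosstab(a, b).to_numpy()
        gamma = goodman_kruskal_gamma(table)
        _, p = cramers_v(table)
        return AssociationScore("gamma", abs(gamma), p)
    if kind_a not in continuous and kind_b not in continuous:
        table = pd.crosstab(a, b).to_numpy()
        v, p = cramers_v(table)
        return AssociationScore("fisher_chi2", v, p)
    # categorical-continuous
    cont, cat = (a, b) if kind_a in continuous else (b, a)
    auc, codes = _logistic_auroc(cont.to_numpy(dtype=float), cat.to_numpy(), rng)
    score = 2.0 * abs(auc - 0.5)
    if len(np.unique(codes)) == 2:
        g0 = cont.to_numpy(dtype=float)[codes == 0]
        g1 = cont.to_numpy(dtype=float)[codes == 1]
        p = float(stats.mannwhitneyu(g0, g1).pvalue)
    else:
        arms = [cont.to_numpy(dtype=float)[codes == c] for c in np.unique(codes)]
        p = float(stats.kruskal(*arms).pvalue)
    return AssociationScore("logistic_auroc", float(score), p)


def adjusted_balanced_accuracy(confusion: np.ndarray) -> float:
    """Mean over classes of (sensitivity_c + specificity_c) / 2."""
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = m.sum()
    scores = []
    for c in range(m.shape[0]):
        support = m[c].sum()
        if support == 0:
            warnings.warn(f"class {c} has no instances; skipped", stacklevel=2)
            continue
        tp = m[c, c]
        fp = m[:, c].sum() - tp
        tn = total - support - fp
        sens = tp / support
        if tn + fp > 0:
            scores.append((sens + tn / (tn + fp)) / 2.0)
        else:  # no negatives exist: specificity is vacuous
            scores.append(sens)
    if not scores:
        raise ValueError("no classes with instances")
    return float(np.mean(scores))


def adjusted_auprc(scores, labels, clip: bool = True):
    """AU-PRC rescaled against the chance level of the same labels.

    ``(AUPRC - prevalence) / (1 - prevalence)``; negative values (worse than
    chance) are clipped to 0 by default while the raw AU-PRC is returned
    alongside.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    raw = float(average_precision_score(y, s))
    prevalence = float(y.mean())
    adj = (raw - prevalence) / (1.0 - prevalence)
    if clip:
        adj = max(adj, 0.0)
    return float(adj), raw, prevalence


def predictability(
    features: np.ndarray,
    target,
    kind: str,
    patient_groups: Sequence,
    k: int = 5,
    cv_folds: int = 5,
) -> float:
    """k-NN predictability of a target from features under grouped CV.

    AU-ROC (micro one-vs-rest for multiclass) for ``kind="classification"``;
    |Spearman rho| of out-of-fold predictions for ``kind="regression"``.
    Folds never split a patient.
    """
    X = np.asarray(features, dtype=float)
    groups = np.asarray(patient_groups)
    if len(np.unique(groups)) < cv_folds:
        raise ValueError("fewer patient groups than folds")
    gkf = GroupKFold(n_splits=cv_folds)
    if kind == "classification":
        y, _ = pd.factorize(pd.Series(target))
        classes = np.unique(y)
        oof = np.zeros((len(y), len(classes)))
        for tr, te in gkf.split(X, y, groups):
            model = KNeighborsClassifier(n_neighbors=min(k, len(tr))).fit(X[tr], y[tr])
            prob = model.predict_proba(X[te])
            for ci, cls in enumerate(model.classes_):
                oof[te, cls] = prob[:, ci]
        if len(classes) == 2:
            return float(roc_auc_score(y, oof[:, 1]))
        return float(roc_auc_score(y, oof, multi_class="ovr", average="micro"))
    elif kind == "regression":
        y = np.asarray(target, dtype=float)
        oof = np.zeros(len(y))
        for tr, te in gkf.split(X, y, groups):
            model = KNeighborsRegressor(n_neighbors=min(k, len(tr))).fit(X[tr], y[tr])
            oof[te] = model.predict(X[te])
        if np.ptp(oof) == 0:
            return 0.0
        return float(abs(stats.spearmanr(oof, y).statistic))
    raise ValueError("kind must be 'classification' or 'regression'")
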