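"""LOSO-validated sigmoid SVM with per-block PCA, SVM-RFE-CBR and balance rule.

Per leave-one-subject-out fold the pipeline refits everything on training
rows only: train-median imputation of undefined features, median/MAD
normalization, one PCA per feature block (HRV, BAND, MPC) retaining the
smallest leading set explaining >= 95% of variance, then a C-SVM with sigmoid
kernel.  Cost and gamma are searched jointly over a 15-value log grid from
0.1 to 1000 (225 pairs); the selected model maximizes pooled accuracy subject
to a balance constraint (both per-class recalls above 60%), falling back to
best unbalanced accuracy when no grid point is balanced.

Feature relevance is probed with nonlinear SVM recursive feature elimination
using the margin-objective sensitivity criterion, with a correlation-bias
reduction step: highly correlated components are grouped and each member's
criterion is evaluated with its group-mates temporarily excluded, so that
redundant copies cannot mask each other's relevance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .fusion import BLOCKS, CaseDataset, block_of

__all__ = [
    "FoldModel",
    "EvaluationReport",
    "make_grid",
    "is_balanced",
    "fit_block_pca",
    "svm_rfe_cbr",
    "loso_evaluate",
    "classify_nature",
    "report",
]


def make_grid(n: int = 15, lo: float = 0.1, hi: float = 1000.0) -> np.ndarray:
    """Log-spaced hyperparameter candidates, endpoints inclusive."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


# ---------------------------------------------------------------------------
# Per-fold preparation
# ---------------------------------------------------------------------------

@dataclass
class BlockPCA:
    """PCA for one feature block with the >=95%-variance retention rule."""

    columns: list[str]
    mean: np.ndarray
    components: np.ndarray            # (n_comp, n_features)
    n_components: int
    explained: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) @ self.components.T


def fit_block_pca(x: np.ndarray, columns: list[str],
                  var_target: float = 0.95) -> BlockPCA | None:
    """Fit a PCA on one block and keep the smallest set reaching ``var_target``.

    Returns None for a constant (zero-variance) block, which is dropped.
    """
    if x.shape[1] == 0:
        return None
    pca = PCA()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pca.fit(x)
    ev = pca.explained_variance_ratio_
    if not np.isfinite(ev).any() or np.allclose(pca.explained_variance_, 0):
        return None
    n_comp = int(np.searchsorted(np.cumsum(ev), var_target) + 1)
    n_comp = min(n_comp, len(ev))
    return BlockPCA(columns=list(columns), mean=pca.mean_,
                    components=pca.components_[:n_comp],
                    n_components=n_comp, explained=ev[:n_comp])


@dataclass
class FoldModel:
    """Everything fitted on one fold's training rows."""

    fold_subject: str
    medians: pd.Series
    mads: pd.Series
    kept_features: list[str]
    pcas: dict[str, BlockPCA]
    component_names: list[str]
    z_train: np.ndarray
    y_train: np.ndarray
    z_val: np.ndarray
    y_val: np.ndarray
    val_index: np.ndarray
    dropped_features: list[str] = field(default_factory=list)


def _prepare_fold(train: pd.DataFrame, val: pd.DataFrame, subject: str,
                  features: list[str], var_target: float) -> FoldModel | None:
    y_tr = train["label"].to_numpy()
    if len(np.unique(y_tr)) < 2:
        return None
    med = train[features].median()
    xtr = train[features].fillna(med)
    xval = val[features].fillna(med)
    mad = (xtr - med).abs().median()
    keep = [f for f in features if np.isfinite(med[f]) and mad[f] > 0]
    dropped = [f for f in features if f not in keep]
    xtr = (xtr[keep] - med[keep]) / mad[keep]
    xval = (xval[keep] - med[keep]) / mad[keep]

    pcas: dict[str, BlockPCA] = {}
    z_tr_parts, z_val_parts, comp_names = [], [], []
    for block in BLOCKS:
        cols = [c for c in keep if block_of(c) == block]
        model = fit_block_pca(xtr[cols].to_numpy(), cols, var_target) if cols else None
        if model is None:
            continue
        pcas[block] = model
        z_tr_parts.append(model.transform(xtr[cols].to_numpy()))
        z_val_parts.append(model.transform(xval[cols].to_numpy()))
        comp_names += [f"{block}_pc{i + 1}" for i in range(model.n_components)]
    if not z_tr_parts:
        return None
    return FoldModel(
        fold_subject=subject, medians=med, mads=mad, kept_features=keep,
        pcas=pcas, component_names=comp_names,
        z_train=np.hstack(z_tr_parts), y_train=y_tr,
        z_val=np.hstack(z_val_parts), y_val=val["label"].to_numpy(),
        val_index=val.index.to_numpy(), dropped_features=dropped,
    )


def prepare_folds(dataset: CaseDataset,
                  var_target: float = 0.95) -> list[FoldModel]:
    """Build one leakage-safe :class:`FoldModel` per museum subject."""
    features = [c for c in dataset.df.columns
                if c.startswith(("hrv_", "bp_", "mpc_"))]
    folds = []
    for subject in dataset.subjects:
        val = dataset.museum[dataset.museum["subject_id"] == subject]
        train = dataset.df[dataset.df["subject_id"] != subject]
        fm = _prepare_fold(train, val, subject, features, var_target)
        if fm is not None:
            folds.append(fm)
    if len(folds) < 3:
        raise ValueError("need at least 3 usable LOSO folds")
    return folds


# ---------------------------------------------------------------------------
# Evaluation helpers
# ---------------------------------------------------------------------------

def _positive_class(labels: np.ndarray, target: str) -> str:
    if target == "nature":
        return "virtual"
    return "high"


def is_balanced(confusion: dict[str, float], balance_min: float = 60.0) -> bool:
    """Balance criterion: both per-class recalls strictly above ``balance_min``.

    ``confusion`` holds row-normalized percentages with ``true_high`` the
    recall of the high/positive class and ``true_low`` of the low/negative
    class.
    """
    return (confusion["true_high"] > balance_min
            and confusion["true_low"] > balance_min)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray,
               pos: str) -> dict[str, float]:
    """Row-normalized 2x2 confusion in percent.

    ``true_high``/``false_high`` split the actual-positive row;
    ``false_low``/``true_low`` split the actual-negative row.
    """
    is_pos = y_true == pos
    pred_pos = y_pred == pos
    n_pos, n_neg = is_pos.sum(), (~is_pos).sum()
    th = float(100.0 * (is_pos & pred_pos).sum() / n_pos) if n_pos else np.nan
    tl = float(100.0 * (~is_pos & ~pred_pos).sum() / n_neg) if n_neg else np.nan
    return {"true_high": th, "false_high": 100.0 - th,
            "false_low": 100.0 - tl, "true_low": tl}


def _f_score(y_true: np.ndarray, y_pred: np.ndarray, pos: str) -> float:
    tp = ((y_true == pos) & (y_pred == pos)).sum()
    fp = ((y_true != pos) & (y_pred == pos)).sum()
    fn = ((y_true == pos) & (y_pred != pos)).sum()
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else np.nan


def _pooled_predictions(folds: list[FoldModel], c: float, gamma: float,
                        component_names: list[str] | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit per fold and pool validation predictions.

    ``component_names`` restricts each fold to the named components (matched
    per fold, since per-block PCA sizes can differ across folds).
    """
    yt, yp, idx = [], [], []
    for fm in folds:
        if component_names is None:
            cols = np.arange(fm.z_train.shape[1])
        else:
            pos = {n: i for i, n in enumerate(fm.component_names)}
            cols = np.array(sorted(pos[n] for n in component_names if n in pos))
            if len(cols) == 0:
                cols = np.arange(fm.z_train.shape[1])
        svm = SVC(kernel="sigmoid", C=c, gamma=gamma)
        svm.fit(fm.z_train[:, cols], fm.y_train)
        yp.append(svm.predict(fm.z_val[:, cols]))
        yt.append(fm.y_val)
        idx.append(fm.val_index)
    return np.concatenate(yt), np.concatenate(yp), np.concatenate(idx)


def _score_grid(folds: list[FoldModel], grid: np.ndarray, pos: str,
                balance_min: float):
    """Joint (C, gamma) search maximizing pooled accuracy under balance."""
    best_bal, best_any = None, None
    for c in grid:
        for g in grid:
            yt, yp, _ = _pooled_predictions(folds, c, g)
            acc = float(np.mean(yt == yp)) * 100.0
            conf = _confusion(yt, yp, pos)
            balanced = is_balanced(conf, balance_min)
            key = (acc, -abs(conf["true_high"] - conf["true_low"]), -c, -g)
            entry = (key, c, g, acc, conf, balanced)
            if best_any is None or key > best_any[0]:
                best_any = entry
            if balanced and (best_bal is None or key > best_bal[0]):
                best_bal = entry
    return best_bal if best_bal is not None else best_any


# ---------------------------------------------------------------------------
# SVM-RFE with correlation-bias reduction
# ---------------------------------------------------------------------------

def _margin_objective(a: np.ndarray, k: np.ndarray) -> float:
    """W^2 = sum_ij alpha_i y_i alpha_j y_j K_ij over support vectors."""
    return float(a @ k @ a)


def svm_rfe_cbr(x: np.ndarray, y: np.ndarray, c: float = 1.0,
                gamma: float = 0.1, corr_threshold: float = 0.85) -> np.ndarray:
    """Rank features by recursive elimination with correlation-bias reduction.

    Returns an array ``ranks`` with ``ranks[f] = 1`` for the most relevant
    feature.  At each iteration one sigmoid-SVM is fitted on the surviving
    features; each feature's criterion is the drop in the margin objective
    W^2 when it is removed, evaluated with its correlated group-mates
    (pairwise |r| > ``corr_threshold``) temporarily excluded so correlated
    copies do not dilute each other's measured relevance.  The
    lowest-criterion feature is removed per iteration.
    """
    x = np.asarray(x, dtype=float)
    p = x.shape[1]
    if p < 1:
        raise ValueError("need at least one feature")
    ranks = np.zeros(p, dtype=int)
    alive = list(range(p))
    next_rank = p
    y01 = (y == np.unique(y)[-1]).astype(float) * 2 - 1
    while len(alive) > 1:
        xs = x[:, alive]
        try:
            svm = SVC(kernel="sigmoid", C=c, gamma=gamma, max_iter=100_000)
            svm.fit(xs, y01)
            if svm.fit_status_ != 0:
                raise RuntimeError("libsvm reported non-convergence")
            sv = svm.support_
            a = svm.dual_coef_.ravel()               # alpha_i * y_i
            crit = _criteria_nonlinear(x, alive, sv, a, gamma, corr_threshold)
        except Exception:
            # fallback: absolute point-biserial correlation with the label
            with np.errstate(invalid="ignore"):
                crit = np.array([abs(np.corrcoef(x[:, f], y01)[0, 1])
                                 for f in alive])
            crit = np.nan_to_num(crit)
        worst = int(np.argmin(crit))
        ranks[alive[worst]] = next_rank
        next_rank -= 1
        alive.pop(worst)
    ranks[alive[0]] = 1
    return ranks


def _criteria_nonlinear(x: np.ndarray, alive: list[int], sv: np.ndarray,
                        a: np.ndarray, gamma: float,
                        corr_threshold: float) -> np.ndarray:
    """Sensitivity criterion per surviving feature, group-mates excluded."""
    xs = x[np.ix_(sv, alive)]
    with np.errstate(invalid="ignore"):
        cc = np.corrcoef(x[:, alive], rowvar=False)
    cc = np.atleast_2d(np.nan_to_num(cc))
    groups = [np.flatnonzero(np.abs(cc[i]) > corr_threshold) for i in
              range(len(alive))]

    gram_all = xs @ xs.T
    crit = np.empty(len(alive))
    for i in range(len(alive)):
        mates = [j for j in groups[i] if j != i]
        base_cols = [j for j in range(len(alive)) if j not in mates]
        xb = xs[:, base_cols]
        gram_base = xb @ xb.T if mates else gram_all
        ii = base_cols.index(i)
        gram_wo = gram_base - np.outer(xb[:, ii], xb[:, ii])
        w_with = _margin_objective(a, np.tanh(gamma * gram_base))
        w_without = _margin_objective(a, np.tanh(gamma * gram_wo))
        crit[i] = abs(w_with - w_without)
    return crit


def _median_rank_order(folds: list[FoldModel], c: float, gamma: float,
                       corr_threshold: float) -> tuple[list[str], pd.Series]:
    """Per-fold RFE rankings aggregated by median rank per component name."""
    per_fold = []
    for fm in folds:
        ranks = svm_rfe_cbr(fm.z_train, fm.y_train, c=c, gamma=gamma,
                            corr_threshold=corr_threshold)
        per_fold.append(pd.Series(ranks, index=fm.component_names))
    table = pd.DataFrame(per_fold)
    med = table.median(axis=0).sort_values(kind="stable")
    return list(med.index), med


# ---------------------------------------------------------------------------
# LOSO evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Pooled LOSO evaluation of one model."""

    case: int
    target: str
    accuracy: float                   # percent
    f_score: float
    confusion: dict[str, float]       # row-normalized percent cells
    balanced: bool
    cost: float
    gamma: float
    selected_per_block: dict[str, tuple[int, int]]
    predictions: pd.DataFrame
    median_ranks: pd.Series | None = None
    n_folds: int = 0
    log: dict = field(default_factory=dict)

    @property
    def selected_total(self) -> tuple[int, int]:
        used = sum(u for u, _ in self.selected_per_block.values())
        tot = sum(t for _, t in self.selected_per_block.values())
        return used, tot


def loso_evaluate(dataset: CaseDataset, grid: np.ndarray | None = None,
                  var_target: float = 0.95, balance_min: float = 60.0,
                  feature_selection: bool = True,
                  corr_threshold: float = 0.85) -> EvaluationReport:
    """Leave-one-subject-out evaluation with grid search and feature selection.

    One fold per subject holding museum rows; validation is that subject's
    museum rows only, training is every other subject's rows including
    calibration-stage extras.  After the (cost, gamma) search, components are
    ordered by median RFE rank over folds and the pooled-accuracy-maximizing
    prefix is selected (balance-constrained, ties to the smaller set).
    """
    grid = make_grid() if grid is None else np.asarray(grid, dtype=float)
    folds = prepare_folds(dataset, var_target)
    pos = _positive_class(dataset.df["label"].to_numpy(), dataset.target)

    _, c_best, g_best, acc, conf, balanced = _score_grid(
        folds, grid, pos, balance_min)

    comp_union: list[str] = []
    for fm in folds:
        for name in fm.component_names:
            if name not in comp_union:
                comp_union.append(name)
    med_ranks = None
    sel_names = comp_union
    if feature_selection and len(comp_union) > 1:
        order, med_ranks = _median_rank_order(folds, c_best, g_best,
                                              corr_threshold)
        best = None
        for k in range(1, len(order) + 1):
            chosen = order[:k]
            yt, yp, _ = _pooled_predictions(folds, c_best, g_best, chosen)
            a = float(np.mean(yt == yp)) * 100.0
            cf = _confusion(yt, yp, pos)
            bal = is_balanced(cf, balance_min)
            key = (bal, a, -k)
            if best is None or key > best[0]:
                best = (key, chosen, a, cf, bal)
        if best is not None:
            _, sel_names, acc, conf, balanced = best

    # final pooled predictions with the selected subset
    yt, yp, vidx = _pooled_predictions(folds, c_best, g_best, sel_names)
    acc = float(np.mean(yt == yp)) * 100.0
    conf = _confusion(yt, yp, pos)
    balanced = is_balanced(conf, balance_min)

    totals = {b: 0 for b in BLOCKS}
    for name in comp_union:
        totals[name.split("_pc")[0]] += 1
    used = {b: 0 for b in BLOCKS}
    for name in sel_names:
        used[name.split("_pc")[0]] += 1
    selected = {b: (used[b], totals[b]) for b in BLOCKS if totals[b] > 0}

    preds = pd.DataFrame({"row": vidx, "y_true": yt, "y_pred": yp})
    return EvaluationReport(
        case=dataset.case, target=dataset.target,
        accuracy=acc, f_score=_f_score(yt, yp, pos), confusion=conf,
        balanced=bool(balanced), cost=float(c_best), gamma=float(g_best),
        selected_per_block=selected, predictions=preds,
        median_ranks=med_ranks, n_folds=len(folds),
        log={"dropped_features": folds[0].dropped_features,
             "grid_size": len(grid)},
    )


def classify_nature(records: pd.DataFrame, grid: np.ndarray | None = None,
                    **kw) -> EvaluationReport:
    """Real-vs-virtual museum classifier: LOSO with target = condition."""
    from .fusion import build_case

    ds = build_case(records, case=1, target="nature")
    return loso_evaluate(ds, grid=grid, **kw)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Summary table: one row per (case, target) evaluation.

    Unbalanced models render their accuracy as ``(TN<60)`` / ``(TP<60)``;
    the accuracy delta is computed against the same target's Case 1 row.
    """
    case1_acc = {r.target: r.accuracy for r in reports
                 if r.case == 1 and r.balanced}
    rows = []
    for r in reports:
        if r.balanced:
            acc_cell = f"{r.accuracy:.2f}%"
        else:
            which = "TN" if r.confusion["true_low"] <= 60 else "TP"
            acc_cell = f"({which}<60)"
        delta = ""
        if r.case != 1 and r.balanced and r.target in case1_acc:
            delta = f"{r.accuracy - case1_acc[r.target]:+.2f}%"
        used, tot = r.selected_total
        row = {"case": r.case, "target": r.target, "accuracy": acc_cell,
               "f_score": round(r.f_score, 2) if r.balanced else "-",
               "delta_accuracy": delta,
               "true_high": round(r.confusion["true_high"], 2),
               "false_high": round(r.confusion["false_high"], 2),
               "false_low": round(r.confusion["false_low"], 2),
               "true_low": round(r.confusion["true_low"], 2),
               "features_total": f"{used}/{tot}"}
        for b, (u, t) in r.selected_per_block.items():
            row[f"features_{b.lower()}"] = f"{u}/{t}"
        rows.append(row)
    return pd.DataFrame(rows)
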