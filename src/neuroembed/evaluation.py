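"""Task-typed evaluation of embedding quality.

The protocol: clinical variables are typed quantitative | categorical |
survival and grouped into named categories; each is predicted from the
embedding matrix with the model family matched to its type (ridge
regression, L2 logistic regression, random survival forest) under
5-fold cross-validation with per-fold grid search and minority-class
random oversampling (training folds only).  Out-of-fold predictions
are concatenated across folds before scoring: weighted F1 and AUROC
for categorical variables, R² for quantitative, Harrell's C-index and
integrated Brier score for survival.  Methods are compared variable-by-
variable with Wilcoxon signed-rank tests (Pratt zero handling, exact
null for n <= 25) under Bonferroni correction.  Exploratory summaries:
per-category 2-component CCA against the embeddings with the first-
variate R² per category ("radar" values, summed to a total area), and
a 2-D UMAP neighborhood projection (15 neighbors).

Unstated-in-protocol choices pinned here so results are reproducible:
penalty grids are 7 log-spaced values 1e-3..1e3; survival forests
search {100, 300} trees x {3, 6} depth; oversampling duplicates
minority rows with replacement to class parity; standardization and
oversampling statistics always come from training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.cross_decomposition import CCA
from sklearn.impute import KNNImputer
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import f1_score, roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sksurv.ensemble import RandomSurvivalForest
from sksurv.metrics import concordance_index_censored, integrated_brier_score
from sksurv.util import Surv

PENALTY_GRID = np.logspace(-3, 3, 7)
RSF_GRID = {"n_estimators": [100, 300], "max_depth": [3, 6]}
TASKS = ("quantitative", "categorical", "survival")


# ---------------------------------------------------------------------------
# clinical table preparation
# ---------------------------------------------------------------------------

@dataclass
class ClinicalTable:
    data: pd.DataFrame                 # index: patient_id
    category_map: dict                 # variable -> {category, type}
    dropped: list = field(default_factory=list)

    def variables(self, var_type: str | None = None):
        out = [v for v in self.data.columns if v in self.category_map]
        if var_type:
            out = [v for v in out if self.category_map[v]["type"] == var_type]
        return out

    def category(self, name: str):
        return [v for v in self.variables()
                if self.category_map[v]["category"] == name]


def prepare_clinical_table(raw: pd.DataFrame, category_map: dict,
                           missing_threshold: float = 0.15,
                           k: int = 140) -> ClinicalTable:
    """Drop too-missing variables, standardize, kNN-impute the rest.

    Variables with missing fraction >= ``missing_threshold`` are
    dropped.  Quantitative variables are z-standardized; remaining
    missing cells are filled with the mean of the ``k`` nearest rows
    (Euclidean distance over the standardized matrix, ``k`` capped at
    n-1).  Categorical imputations are rounded to the nearest observed
    level code.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = raw.copy()
    if "patient_id" in df.columns:
        df = df.set_index("patient_id")
    dropped = []
    for var in list(df.columns):
        if var not in category_map:
            continue
        if df[var].isna().mean() >= missing_threshold:
            df = df.drop(columns=[var])
            dropped.append(var)
    kept = [v for v in df.columns if v in category_map]
    if not kept:
        raise ValueError("all variables dropped by the missingness filter")
    work = pd.DataFrame(index=df.index)
    cat_codes: dict[str, pd.Index] = {}
    for var in kept:
        vtype = category_map[var]["type"]
        if vtype == "categorical" and not pd.api.types.is_numeric_dtype(df[var]):
            codes = df[var].astype("category")
            cat_codes[var] = codes.cat.categories
            col = codes.cat.codes.astype(float).replace(-1, np.nan)
        else:
            col = df[var].astype(float)
        if vtype == "quantitative":
            sd = col.std(ddof=0)
            col = (col - col.mean()) / (sd if sd > 0 else 1.0)
        work[var] = col
    k_eff = min(k, len(work) - 1)
    if work.isna().any().any():
        imputer = KNNImputer(n_neighbors=k_eff, weights="uniform")
        filled = pd.DataFrame(imputer.fit_transform(work),
                              index=work.index, columns=work.columns)
    else:
        filled = work
    for var, cats in cat_codes.items():
        filled[var] = filled[var].round().clip(0, len(cats) - 1)
    return ClinicalTable(data=filled, category_map=category_map, dropped=dropped)


# ---------------------------------------------------------------------------
# cross-validated prediction
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    task: str
    ids: list
    y: np.ndarray                      # labels / values / (event, time)
    oof_pred: np.ndarray               # proba[,1] | regression | risk score
    oof_label: np.ndarray | None       # argmax labels (categorical)
    fold_of: np.ndarray
    fold_params: list
    surv_times: np.ndarray | None = None   # time grid for survival curves
    surv_probs: np.ndarray | None = None   # (n, len(times)) oof S(t)


def _oversample(Xtr, ytr, rng):
    """Random duplication with replacement to class parity."""
    classes, counts = np.unique(ytr, return_counts=True)
    n_max = counts.max()
    idx_all = [np.arange(len(ytr))[ytr == c] for c in classes]
    keep = []
    for idx, cnt in zip(idx_all, counts):
        keep.append(idx)
        if cnt < n_max:
            keep.append(rng.choice(idx, size=n_max - cnt, replace=True))
    sel = np.concatenate(keep)
    return Xtr[sel], ytr[sel]


def fit_predict_cv(X, y, task: str, folds: int = 5, seed: int = 0,
                   ids=None, oversample: bool = True,
                   rsf_grid: dict | None = None,
                   inner_cv: int = 3,
                   leaky_select: int | None = None,
                   guarded_select: int | None = None) -> CVResult:
    """Out-of-fold predictions for one variable.

    ``task`` picks the model family; folds are stratified for
    categorical targets.  ``leaky_select``/``guarded_select`` run
    univariate feature screening either on ALL data (a deliberate
    leakage diagnostic) or inside each training fold; both default off.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    if hasattr(X, "values") and hasattr(X, "patient_ids"):  # EmbeddingMatrix
        ids = list(X.patient_ids)
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    n = len(X)
    ids = list(ids) if ids is not None else list(range(n))
    rng = np.random.default_rng(seed)

    if task == "survival":
        event = np.asarray(y["event"], dtype=bool)
        time = np.asarray(y["time"], dtype=float)
        y_arr = Surv.from_arrays(event=event, time=time)
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        strata = None
    elif task == "categorical":
        y_arr = np.asarray(y)
        classes, counts = np.unique(y_arr, return_counts=True)
        if counts.min() < folds:
            raise ValueError(f"class with {counts.min()} members < {folds} folds")
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        strata = y_arr
    else:
        y_arr = np.asarray(y, dtype=float)
        if np.allclose(y_arr, y_arr[0]):
            raise ValueError("constant target")
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        strata = None

    def _screen(Xa, ya, m):
        yv = ya if task != "survival" else np.asarray(y["time"])[: len(Xa)]
        yv = np.asarray(yv, dtype=float)
        c = np.abs(np.corrcoef(Xa.T, yv)[:-1, -1])
        c = np.nan_to_num(c)
        return np.argsort(-c)[:m]

    cols_global = None
    if leaky_select:
        cols_global = _screen(X, y_arr if task != "survival" else None, leaky_select)

    oof_pred = np.full(n, np.nan)
    oof_label = np.empty(n, dtype=object) if task == "categorical" else None
    fold_of = np.full(n, -1)
    fold_params = []
    surv_times = surv_probs = None
    if task == "survival":
        horizon = np.quantile(time, 0.95)
        surv_times = np.linspace(max(time.min(), 1e-3), horizon, 32)
        surv_probs = np.full((n, len(surv_times)), np.nan)

    for f, (tr, te) in enumerate(splitter.split(X, strata)):
        Xtr, Xte = X[tr], X[te]
        cols = cols_global
        if guarded_select:
            cols = _screen(Xtr, y_arr[tr] if task != "survival" else None,
                           guarded_select)
        if cols is not None:
            Xtr, Xte = Xtr[:, cols], Xte[:, cols]
        if task == "categorical":
            ytr = y_arr[tr]
            if oversample:
                Xtr, ytr = _oversample(Xtr, ytr, rng)
            pipe = Pipeline([("scale", StandardScaler()),
                             ("est", LogisticRegression(max_iter=2000))])
            gs = GridSearchCV(pipe, {"est__C": PENALTY_GRID}, cv=inner_cv,
                              scoring="f1_weighted", n_jobs=1)
            gs.fit(Xtr, ytr)
            proba = gs.predict_proba(Xte)
            pos = list(gs.best_estimator_.named_steps["est"].classes_)
            if len(pos) == 2:
                oof_pred[te] = proba[:, 1]
            else:
                oof_pred[te] = proba.max(axis=1)
            labels = gs.predict(Xte)
            for j, t in enumerate(te):
                oof_label[t] = labels[j]
            fold_params.append(gs.best_params_)
        elif task == "quantitative":
            pipe = Pipeline([("scale", StandardScaler()), ("est", Ridge())])
            gs = GridSearchCV(pipe, {"est__alpha": PENALTY_GRID}, cv=inner_cv,
                              scoring="r2", n_jobs=1)
            gs.fit(Xtr, y_arr[tr])
            oof_pred[te] = gs.predict(Xte)
            fold_params.append(gs.best_params_)
        else:
            grid = rsf_grid if rsf_grid is not None else RSF_GRID
            gs = GridSearchCV(RandomSurvivalForest(random_state=seed, n_jobs=1),
                              grid, cv=inner_cv, n_jobs=1)
            gs.fit(Xtr, y_arr[tr])
            oof_pred[te] = gs.predict(Xte)
            fns = gs.best_estimator_.predict_survival_function(Xte)
            for j, t in enumerate(te):
                # step functions are constant beyond their fitted range
                ts = np.clip(surv_times, fns[j].x[0], fns[j].x[-1])
                surv_probs[t] = fns[j](ts)
            fold_params.append(gs.best_params_)
        fold_of[te] = f
    assert (fold_of >= 0).all(), "every patient must be predicted exactly once"
    return CVResult(task=task, ids=ids, y=y_arr, oof_pred=oof_pred,
                    oof_label=oof_label, fold_of=fold_of,
                    fold_params=fold_params,
                    surv_times=surv_times, surv_probs=surv_probs)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score(result: CVResult) -> dict:
    """Metrics on the concatenated out-of-fold predictions."""
    if result.task == "categorical":
        y = result.y
        labels = np.asarray([v for v in result.oof_label])
        out = {"f1_weighted": float(f1_score(y, labels, average="weighted"))}
        classes = np.unique(y)
        if len(classes) == 2:
            pos = classes[1]
            out["auroc"] = float(roc_auc_score(y == pos, result.oof_pred))
            fpr, tpr, thr = roc_curve(y == pos, result.oof_pred)
            out["roc_points"] = pd.DataFrame({"fpr": fpr, "tpr": tpr,
                                              "threshold": thr})
        return out
    if result.task == "quantitative":
        y = result.y
        sse = float(np.sum((y - result.oof_pred) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        return {"r2": 1.0 - sse / sst}
    event = result.y["event"].astype(bool)
    time = result.y["time"].astype(float)
    cindex = concordance_index_censored(event, time, result.oof_pred)[0]
    out = {"c_index": float(cindex)}
    if result.surv_probs is not None and not np.isnan(result.surv_probs).any():
        # clip the grid strictly inside the observed follow-up range
        lo, hi = time.min(), time.max()
        keep = (result.surv_times > lo) & (result.surv_times < hi)
        try:
            ibs = integrated_brier_score(result.y, result.y,
                                         result.surv_probs[:, keep],
                                         result.surv_times[keep])
            out["integrated_brier"] = float(ibs)
        except ValueError:
            out["integrated_brier"] = np.nan
    return out


def km_null_integrated_brier(y) -> float:
    """Integrated Brier score of the Kaplan–Meier marginal (null model)."""
    from sksurv.nonparametric import kaplan_meier_estimator
    event = y["event"].astype(bool)
    time = y["time"].astype(float)
    kt, ks = kaplan_meier_estimator(event, time)
    grid = np.linspace(time.min(), np.quantile(time, 0.95), 32)
    grid = grid[(grid > time.min()) & (grid < time.max())]
    sf = np.interp(grid, kt, ks)
    probs = np.tile(sf, (len(time), 1))
    return float(integrated_brier_score(y, y, probs, grid))


# ---------------------------------------------------------------------------
# survival stratification
# ---------------------------------------------------------------------------

def stratify_survival(risks, time, event):
    """Median split of predicted risks (ties below-median), Kaplan–Meier
    per group, and a two-sample log-rank test."""
    risks = np.asarray(risks, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(risks) < 4:
        raise ValueError("need at least 4 patients to stratify")
    if np.all(risks == risks[0]):
        raise ValueError("all risks identical; cannot stratify")
    med = np.median(risks)
    high = risks > med
    lr = logrank_test(time[high], time[~high], event[high], event[~high])
    from lifelines import KaplanMeierFitter
    tables = {}
    for name, sel in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter().fit(time[sel], event[sel], label=name)
        tables[name] = km.survival_function_.reset_index().rename(
            columns={"timeline": "time", name: "survival"})
    return {"high_mask": high, "logrank_statistic": float(lr.test_statistic),
            "p_value": float(lr.p_value), "km_tables": tables,
            "group_sizes": {"high": int(high.sum()), "low": int((~high).sum())}}


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------

def _signed_rank(diffs: np.ndarray):
    """Two-sided Wilcoxon signed-rank p-value, Pratt zero handling;
    exact null for n <= 25 (no zeros), normal approximation otherwise."""
    diffs = np.asarray(diffs, dtype=float)
    if np.all(diffs == 0):
        return 0.0, 1.0
    if len(diffs) <= 25 and not np.any(diffs == 0):
        res = stats.wilcoxon(diffs, method="exact")
    else:
        res = stats.wilcoxon(diffs, zero_method="pratt", method="approx",
                             correction=False)
    return float(res.statistic), float(res.pvalue)


def compare_methods(score_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank tests between methods.

    ``score_table``: rows = variables, columns = methods, cells = the
    per-variable score of that method.  Reports raw and Bonferroni-
    corrected p-values (multiplied by the number of pairwise
    comparisons, capped at 1).
    """
    methods = list(score_table.columns)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods to compare")
    if score_table.isna().any().any():
        raise ValueError("methods scored on mismatched variable sets")
    pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1:]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        d = score_table[a].to_numpy() - score_table[b].to_numpy()
        statistic, p = _signed_rank(d)
        rows.append({"method_a": a, "method_b": b, "n": len(d),
                     "median_diff": float(np.median(d)),
                     "statistic": statistic, "p_raw": p,
                     "p_bonferroni": min(1.0, m * p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exploratory summaries
# ---------------------------------------------------------------------------

def cca_radar(X, clinical: ClinicalTable, n_components: int = 2) -> dict:
    """Per-category CCA first-variate R² and the summed "radar area".

    For each clinical category, a ``n_components``-component CCA is fit
    between the embedding matrix and that category's variables; the
    squared Pearson correlation between the paired FIRST canonical
    variates is reported.  Categories with fewer than 2 variables fall
    back to 1 component and are flagged.
    """
    if hasattr(X, "values") and hasattr(X, "patient_ids"):
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    cats = sorted({v["category"] for v in clinical.category_map.values()
                   if v["type"] != "survival"})
    per_category, flags = {}, {}
    for cat in cats:
        cols = [v for v in clinical.category(cat)
                if clinical.category_map[v]["type"] != "survival"]
        if not cols:
            continue
        Y = clinical.data[cols].to_numpy(dtype=np.float64)
        nc = min(n_components, Y.shape[1], X.shape[1])
        flags[cat] = "reduced_components" if nc < n_components else "ok"
        if len(X) <= nc:
            raise ValueError("need n > number of CCA components")
        cca = CCA(n_components=nc, max_iter=1000)
        U, V = cca.fit_transform(X, Y)
        r = np.corrcoef(U[:, 0], V[:, 0])[0, 1]
        per_category[cat] = float(r ** 2)
    return {"per_category": per_category,
            "total_area": float(sum(per_category.values())),
            "flags": flags}


def project_2d(X, n_neighbors: int = 15, seed: int = 0) -> np.ndarray:
    """2-D neighborhood-preserving projection (UMAP), deterministic
    under a fixed seed."""
    if hasattr(X, "values") and hasattr(X, "patient_ids"):
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    if len(X) <= n_neighbors:
        raise ValueError(f"need n > n_neighbors ({n_neighbors})")
    import umap

    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        random_state=seed)
    return np.asarray(reducer.fit_transform(X), dtype=np.float64)
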