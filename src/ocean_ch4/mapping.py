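"""Statistical gap-filling of the dCH4 climatology.

Two model families are trained on the inverse-hyperbolic-sine (IHS)
transformed cell-month means against gridded predictors:

* ``ann`` — a feed-forward network with one hidden layer of sigmoid units and
  a linear output, fit with an L2 weight penalty (a practical stand-in for
  Bayesian regularization);
* ``rrf`` — a regression forest of CART trees, each tree capped at 100
  decision splits and grown on a bootstrap row sample.

Each ensemble member trains on a random 70% of rows and is scored on the
held-out 30% (correlation, centered RMSD, normalized standard deviation, all
in IHS space), then maps the full grid; maps are back-transformed with sinh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xarray as xr
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

PREDICTOR_FIELDS = [
    "depth_m", "sst_C", "sss_psu", "npp", "poc_export",
    "po4_uM", "o2_uM", "hydrate",
]

DEFAULT_ANN_ALPHA = 1e-3
MIN_TRAINING_ROWS = 50


def ihs(x):
    """Inverse hyperbolic sine: ln(x + sqrt(x^2 + 1)); odd, defined for x<0."""
    return np.arcsinh(x)


def ihs_inverse(y):
    return np.sinh(y)


# ---------------------------------------------------------------------------
# Training table
# ---------------------------------------------------------------------------

def _feature_frame(depth, predictors: dict, month, log_depth: bool,
                   month_encoding: bool) -> pd.DataFrame:
    cols = {}
    cols["depth"] = np.log10(depth) if log_depth else depth
    cols.update(predictors)
    if month_encoding:
        ang = 2 * np.pi * (np.asarray(month) - 1) / 12.0
        cols["month_sin"] = np.sin(ang)
        cols["month_cos"] = np.cos(ang)
    return pd.DataFrame(cols)


def build_training_table(climatology: xr.Dataset, predictors: xr.Dataset,
                         log_depth: bool = True, month_encoding: bool = True,
                         biology_field: str = "npp") -> pd.DataFrame:
    """Join non-missing climatology cell-months to interpolated predictors.

    ``biology_field`` selects the biological predictor (``npp`` by default;
    a chlorophyll field may be swapped in for the sensitivity test).  Rows
    with any missing predictor are dropped and counted in ``attrs``.
    """
    interp = predictors.interp(lat=climatology["lat"], lon=climatology["lon"],
                               method="nearest")
    month, ilat, ilon = np.nonzero(climatology["count"].values > 0)
    if month.size == 0:
        raise ValueError("climatology has no observed cell-months")
    pred_names = [f if f != "npp" else biology_field
                  for f in PREDICTOR_FIELDS if f != "depth_m"]
    pvals = {name.replace("_nM", ""): interp[name].values[ilat, ilon]
             for name in pred_names}
    depth = interp["depth_m"].values[ilat, ilon]
    table = _feature_frame(depth, pvals, month + 1, log_depth, month_encoding)
    table["target"] = ihs(climatology["dch4_nM"].values[month, ilat, ilon])
    table["month"] = month + 1
    table["ilat"] = ilat
    table["ilon"] = ilon
    n0 = len(table)
    table = table.dropna().reset_index(drop=True)
    table.attrs["dropped_rows"] = n0 - len(table)
    table.attrs["log_depth"] = log_depth
    table.attrs["month_encoding"] = month_encoding
    table.attrs["biology_field"] = biology_field
    return table


def build_prediction_table(predictors: xr.Dataset, log_depth: bool = True,
                           month_encoding: bool = True,
                           biology_field: str = "npp") -> pd.DataFrame:
    """Feature rows for every grid cell and calendar month."""
    nlat, nlon = predictors["lat"].size, predictors["lon"].size
    ilat, ilon = np.meshgrid(np.arange(nlat), np.arange(nlon), indexing="ij")
    ilat, ilon = ilat.ravel(), ilon.ravel()
    frames = []
    pred_names = [f if f != "npp" else biology_field
                  for f in PREDICTOR_FIELDS if f != "depth_m"]
    pvals = {name.replace("_nM", ""): predictors[name].values[ilat, ilon]
             for name in pred_names}
    depth = predictors["depth_m"].values[ilat, ilon]
    for month in range(1, 13):
        f = _feature_frame(depth, pvals, np.full(ilat.size, month),
                           log_depth, month_encoding)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("target", "month", "ilat", "ilon")]


# ---------------------------------------------------------------------------
# Skill metrics
# ---------------------------------------------------------------------------

def taylor_stats(predicted, observed) -> dict:
    """Correlation R, centered RMSD, and normalized standard deviation.

    Satisfies cRMSD^2 = s_p^2 + s_o^2 - 2 s_p s_o R.  Zero-variance inputs are
    flagged (``degenerate=True``) with R set to NaN.
    """
    p = np.asarray(predicted, float)
    o = np.asarray(observed, float)
    sp, so = p.std(), o.std()
    if sp == 0 or so == 0:
        return {"R": np.nan, "crmsd": np.nan, "norm_sd": np.nan,
                "degenerate": True}
    r = float(np.corrcoef(p, o)[0, 1])
    crmsd = float(np.sqrt(np.mean(((p - p.mean()) - (o - o.mean())) ** 2)))
    return {"R": r, "crmsd": crmsd, "norm_sd": float(sp / so),
            "degenerate": False}


# ---------------------------------------------------------------------------
# Members and ensembles
# ---------------------------------------------------------------------------

@dataclass
class MapMember:
    family: str
    seed: int
    model: object
    feature_names: list
    train_idx: np.ndarray
    val_idx: np.ndarray
    skill: dict


def split_rows(n: int, seed: int, train_fraction: float = 0.7):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = int(round(train_fraction * n))
    return perm[:k], perm[k:]


def train_member(table: pd.DataFrame, family: str, seed: int,
                 hidden_units: int = 20, ann_alpha: float = DEFAULT_ANN_ALPHA,
                 n_trees: int = 50, max_splits: int = 100,
                 min_rows: int = MIN_TRAINING_ROWS) -> MapMember:
    """Train one ensemble member on a random 70% split and score the 30%."""
    if len(table) < min_rows:
        raise ValueError(f"training table has {len(table)} rows < floor {min_rows}")
    feats = feature_columns(table)
    x = table[feats].to_numpy(float)
    y = table["target"].to_numpy(float)
    train_idx, val_idx = split_rows(len(table), seed)

    if np.ptp(y[train_idx]) == 0:
        warnings.warn("constant training target; returning constant model")
        const = float(y[train_idx][0])

        class _Const:
            def predict(self, xx):
                return np.full(len(xx), const)

        model = _Const()
    elif family == "ann":
        model = make_pipeline(
            StandardScaler(),
            MLPRegressor(hidden_layer_sizes=(hidden_units,),
                         activation="logistic", solver="lbfgs",
                         alpha=ann_alpha, max_iter=2000,
                         random_state=seed),
        )
        with warnings.catch_warnings():
            # lbfgs hitting its iteration cap still yields a usable fit; the
            # validation score decides whether the member is any good
            from sklearn.exceptions import ConvergenceWarning
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(x[train_idx], y[train_idx])
    elif family == "rrf":
        # max_features=1.0 + bootstrap => bagged CART trees
        model = RandomForestRegressor(
            n_estimators=n_trees, max_leaf_nodes=max_splits + 1,
            max_features=1.0, bootstrap=True, random_state=seed, n_jobs=1,
        )
        model.fit(x[train_idx], y[train_idx])
    else:
        raise ValueError(f"unknown model family {family!r}")

    skill = taylor_stats(model.predict(x[val_idx]), y[val_idx])
    return MapMember(family, seed, model, feats, train_idx, val_idx, skill)


def predict_map(member: MapMember, prediction_table: pd.DataFrame,
                grid_shape: tuple[int, int]) -> np.ndarray:
    """Monthly dCH4 map [nM], shape (12, nlat, nlon), back-transformed."""
    yhat = member.model.predict(prediction_table[member.feature_names].to_numpy(float))
    return ihs_inverse(yhat).reshape((12,) + grid_shape).astype(np.float32)


@dataclass
class MapEnsemble:
    members: list = field(default_factory=list)
    maps: np.ndarray | None = None        # (n_members, 12, nlat, nlon), nM
    families: np.ndarray | None = None
    lat: np.ndarray | None = None
    lon: np.ndarray | None = None

    @property
    def skills(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"family": m.family, "seed": m.seed, **m.skill} for m in self.members]
        )

    def mean_map(self, family: str | None = None) -> np.ndarray:
        sel = slice(None) if family is None else self.families == family
        return self.maps[sel].mean(axis=0)


def generate_ensemble(table: pd.DataFrame, predictors: xr.Dataset,
                      n_members: int = 100, families=("ann", "rrf"),
                      seed: int = 0, **member_kwargs) -> MapEnsemble:
    """Train ``n_members`` per family and map the full grid with each.

    Individual member failures are logged and skipped; the ensemble never
    aborts on one bad member.
    """
    pred_table = build_prediction_table(
        predictors,
        log_depth=table.attrs.get("log_depth", True),
        month_encoding=table.attrs.get("month_encoding", True),
        biology_field=table.attrs.get("biology_field", "npp"),
    )
    grid_shape = (predictors["lat"].size, predictors["lon"].size)
    members, maps, fams = [], [], []
    for fi, family in enumerate(families):
        for i in range(n_members):
            member_seed = seed + 1000 * fi + i
            try:
                m = train_member(table, family, member_seed, **member_kwargs)
            except ValueError as err:  # pragma: no cover - defensive
                warnings.warn(f"member {family}/{member_seed} failed: {err}")
                continue
            members.append(m)
            fams.append(family)
            maps.append(predict_map(m, pred_table, grid_shape))
    ens = MapEnsemble(members, np.stack(maps), np.array(fams),
                      predictors["lat"].values, predictors["lon"].values)
    return ens


# ---------------------------------------------------------------------------
# Regularization selection and linear baselines
# ---------------------------------------------------------------------------

def select_l2_penalty(table: pd.DataFrame, alphas=(1e-5, 1e-4, 1e-3, 1e-2, 1e-1),
                      seed: int = 0, hidden_units: int = 20) -> float:
    """Grid-search the ANN L2 penalty by held-out correlation."""
    best_alpha, best_r = alphas[0], -np.inf
    for alpha in alphas:
        m = train_member(table, "ann", seed, hidden_units=hidden_units,
                         ann_alpha=alpha)
        r = m.skill["R"]
        if np.isfinite(r) and r > best_r:
            best_alpha, best_r = alpha, r
    return best_alpha


def baseline_models(table: pd.DataFrame, seed: int = 0) -> dict:
    """Validation R^2 of OLS baselines under the same 70/30 protocol.

    Returns per-predictor simple-regression R^2 and the multiple-linear R^2,
    computed on the held-out rows in IHS space.  Collinear columns
    (|r| > 0.999) are dropped with a warning.
    """
    feats = feature_columns(table)
    x = table[feats].to_numpy(float)
    # baselines regress on raw predictor values: undo the depth log transform
    # so the linear models face the untransformed power-law relation
    if table.attrs.get("log_depth", False) and "depth" in feats:
        x = x.copy()
        x[:, feats.index("depth")] = 10.0 ** x[:, feats.index("depth")]
    y = table["target"].to_numpy(float)
    train_idx, val_idx = split_rows(len(table), seed)

    keep = list(range(len(feats)))
    corr = np.corrcoef(x[train_idx].T)
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            if j in keep and abs(corr[i, j]) > 0.999:
                warnings.warn(f"dropping collinear predictor {feats[j]}")
                keep.remove(j)
    x = x[:, keep]
    kept = [feats[i] for i in keep]

    def val_r2(xcols):
        xt = sm.add_constant(xcols[train_idx], has_constant="add")
        fit = sm.OLS(y[train_idx], xt).fit()
        xv = sm.add_constant(xcols[val_idx], has_constant="add")
        resid = y[val_idx] - fit.predict(xv)
        tot = np.sum((y[val_idx] - y[val_idx].mean()) ** 2)
        return float(1.0 - np.sum(resid**2) / tot)

    simple = {name: val_r2(x[:, [i]]) for i, name in enumerate(kept)}
    return {"simple_r2": simple, "mlr_r2": val_r2(x), "predictors": kept}


def overfitting_curve(table: pd.DataFrame, hidden_units_grid=(5, 20, 80),
                      seed: int = 0) -> pd.DataFrame:
    """Training vs validation skill across ANN complexity levels."""
    rows = []
    feats = feature_columns(table)
    x = table[feats].to_numpy(float)
    y = table["target"].to_numpy(float)
    for h in hidden_units_grid:
        m = train_member(table, "ann", seed, hidden_units=h)
        train_r = taylor_stats(m.model.predict(x[m.train_idx]), y[m.train_idx])["R"]
        rows.append({"hidden_units": h, "train_R": train_r,
                     "val_R": m.skill["R"]})
    return pd.DataFrame(rows)
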