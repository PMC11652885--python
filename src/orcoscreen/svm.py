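"""RBF-kernel SVM over the (KierA2, SlogP_VSA1) plane.

Training standardizes features to zero mean / unit variance before the
Gaussian kernel; hyperparameters are chosen by seeded k-fold
cross-validation over a log grid with one refinement pass, ties broken by
the smoother boundary (smaller sum of |dual coefficients|).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

ACTIVE, INACTIVE = "active_orthosteric", "inactive"


@dataclass(frozen=True)
class LabeledPoint:
    compound_id: str
    x: tuple[float, float]
    label: str  # active_orthosteric | inactive

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.x)):
            raise ValueError(f"non-finite coordinates for {self.compound_id}")
        if self.label not in (ACTIVE, INACTIVE):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class SVMModel:
    gamma: float
    C: float
    mean: np.ndarray
    scale: np.ndarray
    support_vectors: np.ndarray   # standardized coordinates
    dual_coefficients: np.ndarray
    bias: float
    seed: int
    feature_names: tuple[str, ...] = ("KierA2", "SlogP_VSA1")

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.scale

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(self.standardize(x))
        d2 = ((z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return (np.exp(-self.gamma * d2) @ self.dual_coefficients) + self.bias

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "gamma": self.gamma, "C": self.C,
            "mean": self.mean.tolist(), "scale": self.scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coefficients": self.dual_coefficients.tolist(),
            "bias": self.bias, "seed": self.seed,
            "feature_names": list(self.feature_names),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SVMModel":
        s = str(source)
        text = Path(s).read_text() if "\n" not in s and Path(s).suffix == ".json" else s
        d = json.loads(text)
        return cls(
            gamma=d["gamma"], C=d["C"],
            mean=np.asarray(d["mean"]), scale=np.asarray(d["scale"]),
            support_vectors=np.asarray(d["support_vectors"]),
            dual_coefficients=np.asarray(d["dual_coefficients"]),
            bias=d["bias"], seed=d["seed"],
            feature_names=tuple(d["feature_names"]),
        )


@dataclass(frozen=True)
class CVReport:
    k: int
    loss: float
    fold_assignments: dict[str, int]
    seed: int


def _xy(points: Sequence[LabeledPoint]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([p.x for p in points], dtype=float)
    y = np.array([1 if p.label == ACTIVE else -1 for p in points])
    return X, y


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    return mean, scale


def train(points: Sequence[LabeledPoint], gamma: float, C: float, seed: int = 0) -> SVMModel:
    """Fit a standardized soft-margin RBF SVM; deterministic for fixed inputs."""
    X, y = _xy(points)
    if len(set(y)) < 2:
        raise ValueError("training requires both classes")
    mean, scale = _standardizer(X)
    Z = (X - mean) / scale
    clf = SVC(kernel="rbf", gamma=gamma, C=C, random_state=seed)
    clf.fit(Z, y)
    n_iter = int(np.asarray(clf.n_iter_).max())
    if n_iter >= clf.max_iter > 0:
        raise RuntimeError(f"SVM did not converge within {clf.max_iter} iterations")
    return SVMModel(
        gamma=float(clf._gamma), C=float(C), mean=mean, scale=scale,
        support_vectors=clf.support_vectors_.copy(),
        dual_coefficients=clf.dual_coef_.ravel().copy(),
        bias=float(clf.intercept_[0]), seed=seed,
    )


def predict(model: SVMModel, x: Sequence[float]) -> str:
    """Hard label from the sign of the decision function."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite descriptor input")
    return "retained" if float(model.decision_function(x)[0]) > 0 else "rejected"


def predict_many(model: SVMModel, X: np.ndarray) -> list[str]:
    df = model.decision_function(np.asarray(X, dtype=float))
    return ["retained" if v > 0 else "rejected" for v in df]


def _cv_loss(X: np.ndarray, y: np.ndarray, gamma: float, C: float,
             k: int, seed: int) -> tuple[float, np.ndarray]:
    """k-fold misclassification fraction with per-fold standardization."""
    if k == len(y):  # leave-one-out: stratification is impossible and moot
        skf = KFold(n_splits=k)
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    errs = 0
    assign = np.empty(len(y), dtype=int)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        assign[te] = fold
        mean, scale = _standardizer(X[tr])
        clf = SVC(kernel="rbf", gamma=gamma, C=C)
        clf.fit((X[tr] - mean) / scale, y[tr])
        errs += int(np.sum(clf.predict((X[te] - mean) / scale) != y[te]))
    return errs / len(y), assign


def default_grid(n: int = 13) -> tuple[np.ndarray, np.ndarray]:
    return np.logspace(-3, 3, n), np.logspace(-2, 4, n)


def tune_and_cross_validate(
    points: Sequence[LabeledPoint],
    k: int = 10,
    search_grid: tuple[Sequence[float], Sequence[float]] | None = None,
    seed: int = 0,
    refine: bool = True,
) -> tuple[SVMModel, CVReport]:
    """Grid search (gamma, C) minimizing k-fold CV loss; refit best on all data.

    Ties in CV loss are broken by the smaller sum of |dual coefficients| of
    the full-data refit (preferring the smoother boundary), then by smaller
    (gamma, C).
    """
    X, y = _xy(points)
    if len(set(y)) < 2:
        raise ValueError("both classes required")
    if k > len(points):
        raise ValueError("k cannot exceed the number of points")
    gammas, Cs = search_grid if search_grid is not None else default_grid()

    def search(gammas, Cs):
        best = None
        for g, c in itertools.product(gammas, Cs):
            loss, assign = _cv_loss(X, y, g, c, k, seed)
            if best is None or loss < best[0] - 1e-12:
                model = train(points, g, c, seed)
                best = (loss, float(np.abs(model.dual_coefficients).sum()),
                        g, c, model, assign)
            elif abs(loss - best[0]) <= 1e-12:
                model = train(points, g, c, seed)
                smooth = float(np.abs(model.dual_coefficients).sum())
                if smooth < best[1] - 1e-12:
                    best = (loss, smooth, g, c, model, assign)
        return best

    best = search(gammas, Cs)
    if refine:
        loss0, _, g0, c0, _, _ = best
        gf = g0 * np.logspace(-0.5, 0.5, 5)
        cf = c0 * np.logspace(-0.5, 0.5, 5)
        refined = search(gf, cf)
        if refined[0] <= best[0]:
            best = refined
    loss, _, g, c, model, assign = best
    report = CVReport(
        k=k, loss=loss,
        fold_assignments={p.compound_id: int(f) for p, f in zip(points, assign)},
        seed=seed,
    )
    return model, report


def pair_search(
    descriptor_table: pd.DataFrame,
    labels: dict[str, str],
    k: int = 10,
    seed: int = 0,
    search_grid: tuple[Sequence[float], Sequence[float]] | None = None,
) -> list[tuple[tuple[str, str], float]]:
    """Tune an SVM for every descriptor pair; rank ascending by CV loss.

    Constant and duplicate descriptor columns are skipped with a warning.
    Ties are broken lexicographically by descriptor names.
    """
    cols = list(descriptor_table.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 descriptors for pair search")
    usable = []
    seen_profiles: list[tuple[str, np.ndarray]] = []
    for c in cols:
        v = descriptor_table[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"descriptor {c!r} is constant; skipped")
            continue
        dup = next((name for name, prof in seen_profiles if np.allclose(prof, v)), None)
        if dup is not None:
            warnings.warn(f"descriptor {c!r} duplicates {dup!r}; skipped")
            continue
        seen_profiles.append((c, v))
        usable.append(c)

    results = []
    for a, b in itertools.combinations(sorted(usable), 2):
        pts = [
            LabeledPoint(cid, (float(descriptor_table.at[cid, a]),
                               float(descriptor_table.at[cid, b])), labels[cid])
            for cid in descriptor_table.index
        ]
        _, report = tune_and_cross_validate(pts, k=k, seed=seed,
                                            search_grid=search_grid, refine=False)
        results.append(((a, b), report.loss))
    results.sort(key=lambda r: (r[1], r[0]))
    return results


def decision_map(
    model: SVMModel,
    bounds: tuple[float, float, float, float],
    grid_step: float,
) -> pd.DataFrame:
    """Class label on a regular grid (columns: x, y, decision, label)."""
    x0, x1, y0, y1 = bounds
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    if not all(np.isfinite(bounds)) or x1 < x0 or y1 < y0:
        raise ValueError("invalid bounds")
    xs = np.arange(x0, x1 + grid_step / 2, grid_step)
    ys = np.arange(y0, y1 + grid_step / 2, grid_step)
    if len(xs) == 0 or len(ys) == 0:
        raise ValueError("empty grid")
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    dec = model.decision_function(pts)
    return pd.DataFrame({
        "x": pts[:, 0], "y": pts[:, 1], "decision": dec,
        "label": np.where(dec > 0, "retained", "rejected"),
    })


def table5_points() -> list[LabeledPoint]:
    """The 32 printed descriptor points with activity labels (canonical input)."""
    from .registry import load_fixture

    pts = []
    for rec in load_fixture("T5"):
        pts.append(LabeledPoint(
            compound_id=rec.compound.id,
            x=(rec.extras["kier_a2"], rec.extras["slogp_vsa1"]),
            label=ACTIVE if rec.label.active_orthosteric else INACTIVE,
        ))
    return pts
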