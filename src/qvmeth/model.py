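"""Gradient-boosted regression of logit-transformed methylation levels.

The modelling surface follows the statsmodels convention: a
:class:`MethylationLevelModel` is built from a feature matrix and per-locus
methylation labels; ``fit()`` returns a :class:`MethylationLevelResults`
carrying the trained ensemble, training diagnostics, ``predict`` and
``summary``.  Thin functional wrappers (:func:`train_model`,
:func:`predict_loci`) expose the same operations for pipeline code.

Labels y ∈ [0, 1] are mapped to the real line before fitting.  Two variants
of the transform are provided:

* ``clip`` (default): y′ = logit(clip(y, α, 1−α)) — an ε-logit with ε = α,
  monotone over the whole of [0, 1].
* ``literal``: y′ = −α at y = 0, logit(y) for 0 < y < 1, +α at y = 1 — the
  exact piecewise form with the endpoint constants ±α.  Note this variant is
  not monotone: the endpoints map inside the range of interior values.

α defaults to 10⁻³.  Predictions are mapped back through the logistic
sigmoid and clamped to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xgboost as xgb
from scipy.special import expit

from .errors import (
    AlignmentMismatchError,
    InsufficientDataError,
    LayoutError,
)
from .features import DEFAULT_LAYOUT, FeatureLayout, FeatureVector
from .records import MethylationRecord

DEFAULT_HYPERPARAMS = {"eta": 0.1, "num_round": 1500, "max_depth": 8}


@dataclass(frozen=True)
class TransformConfig:
    """Parameters of the label transform; 0 < alpha < 0.5."""

    alpha: float = 1e-3
    mode: str = "clip"  # 'clip' or 'literal'

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 0.5):
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if self.mode not in ("clip", "literal"):
            raise ValueError(f"mode must be 'clip' or 'literal', got {self.mode}")


def logit_transform(y, cfg: TransformConfig = TransformConfig()):
    """Map methylation fractions to the real line (see module docstring)."""
    y_arr = np.asarray(y, dtype=float)
    if np.any((y_arr < 0) | (y_arr > 1)):
        raise ValueError("methylation level outside [0, 1]")
    if cfg.mode == "clip":
        c = np.clip(y_arr, cfg.alpha, 1.0 - cfg.alpha)
        out = np.log(c) - np.log1p(-c)
    else:
        out = np.empty_like(y_arr)
        zero = y_arr == 0.0
        one = y_arr == 1.0
        mid = ~(zero | one)
        out[zero] = -cfg.alpha
        out[one] = cfg.alpha
        out[mid] = np.log(y_arr[mid]) - np.log1p(-y_arr[mid])
    return float(out) if np.isscalar(y) else out


def inverse_transform(yprime):
    """Logistic sigmoid back-map, clamped to [0, 1]."""
    out = np.clip(expit(np.asarray(yprime, dtype=float)), 0.0, 1.0)
    return float(out) if np.isscalar(yprime) else out


def _as_matrix(features) -> tuple[np.ndarray, str, FeatureLayout]:
    """Accept an ndarray or a list of FeatureVector; return (X, version, layout)."""
    if isinstance(features, np.ndarray):
        return np.atleast_2d(features), DEFAULT_LAYOUT.version, DEFAULT_LAYOUT
    if len(features) == 0:
        return (
            np.empty((0, DEFAULT_LAYOUT.total_length)),
            DEFAULT_LAYOUT.version,
            DEFAULT_LAYOUT,
        )
    versions = {fv.layout_version for fv in features}
    if len(versions) != 1:
        raise LayoutError(f"mixed feature layout versions: {sorted(versions)}")
    return (
        np.vstack([fv.values for fv in features]),
        versions.pop(),
        features[0].layout,
    )


@dataclass
class TrainedModel:
    """Persisted boosted-tree ensemble plus the metadata needed to reuse it."""

    booster: xgb.Booster
    layout_version: str
    flank: int
    transform: TransformConfig
    hyperparams: dict
    seed: int
    provenance: str = ""
    feature_mask: list[str] | None = None

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Predicted y′ (transformed scale) for a feature matrix."""
        layout = FeatureLayout(flank=self.flank)
        if self.feature_mask is not None and X.shape[1] == layout.total_length:
            X = X[:, layout.columns_for(self.feature_mask)]
        return self.booster.predict(xgb.DMatrix(X))

    def predict_levels(self, X: np.ndarray) -> np.ndarray:
        """Predicted methylation fractions in [0, 1]."""
        return inverse_transform(self.predict_raw(X))

    def save(self, path: str | Path) -> Path:
        """Write the model directory: portable booster dump + meta.json."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(str(path / "model.json"))
        meta = {
            "layout_version": self.layout_version,
            "flank": self.flank,
            "transform": {"alpha": self.transform.alpha,
                          "mode": self.transform.mode},
            "hyperparams": self.hyperparams,
            "seed": self.seed,
            "provenance": self.provenance,
            "feature_mask": self.feature_mask,
        }
        with open(path / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        with open(path / "meta.json") as fh:
            meta = json.load(fh)
        booster = xgb.Booster()
        booster.load_model(str(path / "model.json"))
        return cls(
            booster=booster,
            layout_version=meta["layout_version"],
            flank=meta["flank"],
            transform=TransformConfig(**meta["transform"]),
            hyperparams=meta["hyperparams"],
            seed=meta["seed"],
            provenance=meta.get("provenance", ""),
            feature_mask=meta.get("feature_mask"),
        )


class MethylationLevelModel:
    """Boosted-tree regression of per-locus methylation on window features.

    Parameters
    ----------
    features : ndarray (n_loci, n_features) or list of FeatureVector
        Window feature matrix in the fixed layout.
    labels : array-like of fractions or list of MethylationRecord
        Per-locus methylation levels in [0, 1], aligned with ``features``.
    transform : TransformConfig
        Label transform applied before fitting.
    feature_mask : list of family names, optional
        Restrict training to the named feature families (for ablation runs).
    """

    def __init__(
        self,
        features,
        labels,
        transform: TransformConfig = TransformConfig(),
        flank: int = 10,
        feature_mask: list[str] | None = None,
        provenance: str = "",
        min_train_loci: int = 10,
    ):
        X, version, layout = _as_matrix(features)
        if isinstance(labels, (list, tuple)) and labels \
                and isinstance(labels[0], MethylationRecord):
            y = np.array([rec.level for rec in labels], dtype=float)
        else:
            y = np.asarray(labels, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise AlignmentMismatchError(
                f"{X.shape[0]} feature rows vs {y.shape[0]} labels"
            )
        if X.shape[0] < min_train_loci:
            raise InsufficientDataError(
                f"need at least {min_train_loci} training loci, "
                f"got {X.shape[0]}"
            )
        self.layout = FeatureLayout(flank=flank) if layout is None else layout
        if feature_mask is not None:
            X = X[:, self.layout.columns_for(feature_mask)]
        self.X = X
        self.y = y
        self.transform = transform
        self.layout_version = version
        self.flank = flank
        self.feature_mask = feature_mask
        self.provenance = provenance

    @classmethod
    def from_tables(
        cls,
        feature_frame,
        loci: list[MethylationRecord],
        **kwargs,
    ) -> "MethylationLevelModel":
        """Build from a prepdata feature table joined to a loci table.

        ``feature_frame`` is the DataFrame written by the prepdata step
        (columns chrom, start, strand, depth, f...); rows are joined to
        ``loci`` by (chrom, start, strand) and unmatched feature rows raise.
        """
        by_key = {rec.key(): rec for rec in loci}
        labels = []
        for chrom, start, strand in zip(
            feature_frame["chrom"], feature_frame["start"],
            feature_frame["strand"],
        ):
            key = (str(chrom), int(start), str(strand))
            if key not in by_key:
                raise AlignmentMismatchError(
                    f"feature row {key} has no matching locus label"
                )
            labels.append(by_key[key])
        X = feature_frame.drop(
            columns=["chrom", "start", "strand", "depth"]
        ).to_numpy(dtype=float)
        return cls(X, labels, **kwargs)

    def fit(
        self,
        eta: float = 0.1,
        num_round: int = 1500,
        max_depth: int = 8,
        seed: int = 0,
        nthread: int = 1,
        **extra_params,
    ) -> "MethylationLevelResults":
        """Fit the squared-error boosted ensemble on the transformed labels."""
        yprime = logit_transform(self.y, self.transform)
        params = {
            "objective": "reg:squarederror",
            "eta": eta,
            "max_depth": max_depth,
            "seed": seed,
            "nthread": nthread,
            **extra_params,
        }
        dtrain = xgb.DMatrix(self.X, label=yprime)
        booster = xgb.train(params, dtrain, num_boost_round=num_round)
        trained = TrainedModel(
            booster=booster,
            layout_version=self.layout_version,
            flank=self.flank,
            transform=self.transform,
            hyperparams={"eta": eta, "num_round": num_round,
                         "max_depth": max_depth},
            seed=seed,
            provenance=self.provenance,
            feature_mask=self.feature_mask,
        )
        return MethylationLevelResults(model=self, trained=trained)


@dataclass
class MethylationLevelResults:
    """Fit results: the trained ensemble plus training diagnostics."""

    model: MethylationLevelModel
    trained: TrainedModel
    fittedvalues: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.fittedvalues = inverse_transform(
            self.trained.booster.predict(xgb.DMatrix(self.model.X))
        )

    def predict(self, features) -> np.ndarray:
        """Predicted methylation fractions for new feature rows."""
        X, version, _ = _as_matrix(features)
        if version != self.trained.layout_version:
            raise LayoutError(
                f"feature layout {version!r} does not match model layout "
                f"{self.trained.layout_version!r}"
            )
        return self.trained.predict_levels(X)

    @property
    def train_rmse(self) -> float:
        """Root mean squared error on the transformed scale."""
        yprime = logit_transform(self.model.y, self.model.transform)
        pred = self.trained.booster.predict(xgb.DMatrix(self.model.X))
        return float(np.sqrt(np.mean((pred - yprime) ** 2)))

    @property
    def train_pcc(self) -> float:
        """Pearson correlation of fitted vs observed levels."""
        if np.std(self.model.y) == 0 or np.std(self.fittedvalues) == 0:
            return float("nan")
        return float(np.corrcoef(self.model.y, self.fittedvalues)[0, 1])

    def save(self, path: str | Path) -> Path:
        return self.trained.save(path)

    def summary(self) -> str:
        h = self.trained.hyperparams
        mask = ", ".join(self.trained.feature_mask) \
            if self.trained.feature_mask else "all"
        lines = [
            "Methylation level regression (gradient-boosted trees)",
            "=" * 56,
            f"No. loci:        {self.model.X.shape[0]}",
            f"No. features:    {self.model.X.shape[1]} ({mask})",
            f"Transform:       {self.model.transform.mode} "
            f"(alpha={self.model.transform.alpha:g})",
            f"eta:             {h['eta']}",
            f"num_round:       {h['num_round']}",
            f"max_depth:       {h['max_depth']}",
            f"seed:            {self.trained.seed}",
            f"Train RMSE (y'): {self.train_rmse:.4f}",
            f"Train PCC:       {self.train_pcc:.4f}",
        ]
        return "\n".join(lines)


def train_model(
    features,
    labels,
    cfg: TransformConfig = TransformConfig(),
    hyperparams: dict | None = None,
    seed: int = 0,
    nthread: int = 1,
    feature_mask: list[str] | None = None,
    provenance: str = "",
    min_train_loci: int = 10,
) -> TrainedModel:
    """Functional wrapper: fit and return the persistable TrainedModel."""
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    model = MethylationLevelModel(
        features, labels, transform=cfg, feature_mask=feature_mask,
        provenance=provenance, min_train_loci=min_train_loci,
    )
    results = model.fit(
        eta=hp["eta"], num_round=hp["num_round"], max_depth=hp["max_depth"],
        seed=seed, nthread=nthread,
    )
    return results.trained


def predict_loci(
    model: TrainedModel,
    features,
    loci: list[MethylationRecord],
) -> list[MethylationRecord]:
    """Predict per-locus methylation for the given loci.

    ``loci`` supplies the identities (chrom, start, strand) and depths; the
    returned records carry the predicted levels.
    """
    X, version, _ = _as_matrix(features)
    if X.shape[0] == 0:
        return []
    if version != model.layout_version:
        raise LayoutError(
            f"feature layout {version!r} does not match model layout "
            f"{model.layout_version!r}"
        )
    if len(loci) != X.shape[0]:
        raise AlignmentMismatchError(
            f"{X.shape[0]} feature rows vs {len(loci)} loci"
        )
    levels = model.predict_levels(X)
    return [
        MethylationRecord(
            chrom=rec.chrom,
            start=rec.start,
            strand=rec.strand,
            level=float(lv),
            depth=rec.depth,
            score=int(round(1000 * float(lv))),
        )
        for rec, lv in zip(loci, levels)
    ]


def average_strands(
    records: list[MethylationRecord],
) -> list[MethylationRecord]:
    """Collapse per-strand CpG records to site-level records.

    A '+' record at position i pairs with a '−' record at i+1 on the same
    contig (CpG geometry); the pair becomes one record at the forward-strand
    C with the mean level and summed depth.  Unpaired records pass through.
    """
    forward = {(r.chrom, r.start): r for r in records if r.strand == "+"}
    out: list[MethylationRecord] = []
    consumed: set[tuple[str, int]] = set()
    for rec in records:
        if rec.strand == "-":
            key = (rec.chrom, rec.start - 1)
            if key in forward:
                mate = forward[key]
                consumed.add(key)
                out.append(
                    MethylationRecord(
                        chrom=mate.chrom,
                        start=mate.start,
                        strand="+",
                        level=(mate.level + rec.level) / 2.0,
                        depth=mate.depth + rec.depth,
                        score=(mate.score + rec.score) // 2,
                    )
                )
            else:
                out.append(rec)
    for rec in records:
        if rec.strand == "+" and (rec.chrom, rec.start) not in consumed:
            out.append(rec)
    return sorted(out, key=lambda r: (r.chrom, r.start, r.strand))
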