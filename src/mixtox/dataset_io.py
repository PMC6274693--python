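"""Load, validate and serve the toxicity data tables; generate synthetic datasets.

Two fixture tables ship with the package:

``compounds.csv``
    55 pure compounds (aldehydes, cyanogenic compounds, triazine and urea
    herbicides, sulfonamides, trimethoprim) with CAS numbers, curated SMILES
    and experimental / reference-model-predicted −log10(EC50) in mol/L.

``mixtures.csv``
    99 binary combinations with the toxic-unit ratio of the two components,
    the experimental mixture toxicity −log10(EC50mix), reference MLR and
    RBF-network predictions, and the A/B/C/D/T cross-validation subset label
    (T = external test set, 20 rows; A–D partition the 79 training rows).

The synthetic generator produces datasets with a known linear or
radial-basis-function structure plus Gaussian noise, for parameter-recovery
and property tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataLoadError, ParseError, ValidationError

COMPOUND_GROUPS = frozenset(
    {"aldehyde", "cyanogenic", "triazine", "urea", "sulfonamide", "trimethoprim"}
)
SUBSET_LABELS = ("A", "B", "C", "D", "T")

_COMPOUND_COLUMNS = [
    "id", "name", "cas", "smiles", "group",
    "neg_log_ec50_exp", "neg_log_ec50_pred", "residual",
]
_MIXTURE_COLUMNS = [
    "combo_id", "printed_no", "component_a", "component_b", "ratio",
    "neg_log_ec50mix_exp", "mlr_pred", "mlr_residual",
    "rbfnn_pred", "rbfnn_residual", "subset",
]


@dataclass
class CompoundRecord:
    """A pure chemical with its toxicity endpoint (−log10 EC50, mol/L)."""

    id: str
    name: str
    cas: str
    smiles: str
    group: str
    neg_log_ec50_exp: float
    neg_log_ec50_pred: float | None = None


@dataclass
class MixtureRecord:
    """A binary combination described by toxic-unit fractions of its components."""

    combo_id: int
    component_a: str
    component_b: str
    fraction_a: float
    fraction_b: float
    neg_log_ec50mix_exp: float
    mlr_pred: float | None = None
    rbfnn_pred: float | None = None
    subset: str = "A"
    printed_no: int | None = None


@dataclass
class SyntheticDataset:
    """A generated descriptor matrix and response with known structure."""

    X: pd.DataFrame
    y: np.ndarray
    model: str
    coefficients: dict[str, float] | None
    centers: np.ndarray | None
    weights: np.ndarray | None
    width: float | None
    noise_sd: float
    seed: int

    def metadata(self) -> dict:
        """JSON-serializable description of the generating process."""
        return {
            "model": self.model,
            "n": int(len(self.y)),
            "columns": list(self.X.columns),
            "coefficients": self.coefficients,
            "centers": None if self.centers is None else self.centers.tolist(),
            "weights": None if self.weights is None else self.weights.tolist(),
            "width": self.width,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.metadata(), indent=2))


def _data_path(name: str):
    return resources.files("mixtox.data").joinpath(name)


def parse_ratio(text: str) -> tuple[float, float]:
    """Normalize a toxic-unit ratio string ``"a:b"`` to fractions summing to 1.

    >>> parse_ratio("1:1")
    (0.5, 0.5)
    """
    parts = str(text).split(":")
    if len(parts) != 2:
        raise ParseError(f"ratio must be 'a:b', got {text!r}")
    try:
        a, b = float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise ParseError(f"non-numeric ratio part in {text!r}") from exc
    if not np.isfinite(a) or not np.isfinite(b) or a < 0 or b < 0 or a + b <= 0:
        raise ParseError(f"ratio parts must be nonnegative with positive sum: {text!r}")
    return a / (a + b), b / (a + b)


def load_compound_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read the pure-compound table (bundled fixture when *path* is None).

    Returns a DataFrame with one row per compound; raises
    :class:`DataLoadError` on missing columns, duplicate ids or empty input.
    """
    source = _data_path("compounds.csv") if path is None else Path(path)
    try:
        df = pd.read_csv(source)
    except pd.errors.EmptyDataError as exc:
        raise DataLoadError(f"empty compound table: {source}") from exc
    missing = [c for c in _COMPOUND_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise DataLoadError(f"compound table missing columns: {missing}")
    if df.empty:
        raise DataLoadError("compound table has no rows")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"])
        raise DataLoadError(f"duplicate compound ids: {dupes}")
    if not np.isfinite(df["neg_log_ec50_exp"]).all():
        raise DataLoadError("non-finite experimental activity value")
    return df


def load_mixture_table(
    path: str | Path | None = None, compounds: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read the binary-mixture table and attach full-precision toxic-unit fractions.

    Fractions are recomputed from the ``ratio`` string by :func:`parse_ratio`
    (never stored rounded). Component labels are checked against the compound
    table (the bundled one unless *compounds* is given).
    """
    source = _data_path("mixtures.csv") if path is None else Path(path)
    try:
        df = pd.read_csv(source)
    except pd.errors.EmptyDataError as exc:
        raise DataLoadError(f"empty mixture table: {source}") from exc
    missing = [c for c in _MIXTURE_COLUMNS if c not in df.columns and c != "printed_no"]
    if missing:
        raise DataLoadError(f"mixture table missing columns: {missing}")
    if df.empty:
        raise DataLoadError("mixture table has no rows")

    fractions = df["ratio"].map(parse_ratio)
    df = df.assign(
        fraction_a=[f[0] for f in fractions],
        fraction_b=[f[1] for f in fractions],
    )
    bad_subset = set(df["subset"]) - set(SUBSET_LABELS)
    if bad_subset:
        raise DataLoadError(f"unknown subset labels: {sorted(bad_subset)}")

    known = load_compound_table() if compounds is None else compounds
    known_ids = set(known["id"])
    referenced = set(df["component_a"]) | set(df["component_b"])
    unknown = sorted(referenced - known_ids)
    if unknown:
        raise DataLoadError(f"mixture rows reference unknown compounds: {unknown}")
    return df


def write_compound_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_mixture_table(df: pd.DataFrame, path: str | Path) -> None:
    # fractions are derived columns; the ratio string is the stored source
    df.drop(columns=["fraction_a", "fraction_b"], errors="ignore").to_csv(
        path, index=False
    )


def compound_records(df: pd.DataFrame | None = None) -> list[CompoundRecord]:
    """The compound table as a list of typed records."""
    df = load_compound_table() if df is None else df
    return [
        CompoundRecord(
            id=r.id, name=r.name, cas=str(r.cas), smiles=r.smiles, group=r.group,
            neg_log_ec50_exp=float(r.neg_log_ec50_exp),
            neg_log_ec50_pred=float(r.neg_log_ec50_pred),
        )
        for r in df.itertuples()
    ]


def mixture_records(df: pd.DataFrame | None = None) -> list[MixtureRecord]:
    """The mixture table as a list of typed records."""
    df = load_mixture_table() if df is None else df
    return [
        MixtureRecord(
            combo_id=int(r.combo_id), component_a=r.component_a,
            component_b=r.component_b, fraction_a=float(r.fraction_a),
            fraction_b=float(r.fraction_b),
            neg_log_ec50mix_exp=float(r.neg_log_ec50mix_exp),
            mlr_pred=float(r.mlr_pred), rbfnn_pred=float(r.rbfnn_pred),
            subset=r.subset, printed_no=int(r.printed_no),
        )
        for r in df.itertuples()
    ]


# Defaults for the linear generator: the mixture-model coefficient scale, with
# descriptor columns spanning the ranges the three graph descriptors occupy
# (a small triple-bond count, an information content of a few bits, a partial
# charge of order 0.1).
_DEFAULT_LINEAR_COEFFICIENTS = {
    "intercept": -0.405, "ntb": -0.688, "acic2": 1.847, "qmaxc": 63.611,
}
_DEFAULT_RBF_CENTERS = np.array(
    [[0.25, 0.25, 0.6], [0.75, 0.4, 0.25], [0.5, 0.8, 0.8]]
)
_DEFAULT_RBF_WEIGHTS = np.array([2.0, -1.0, 1.5])


def generate_synthetic(
    n: int,
    model: str = "linear",
    coefficients: dict[str, float] | None = None,
    centers: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    width: float = 1.2,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a dataset with known structure plus Gaussian noise.

    ``model="linear"``: descriptor-like columns (ntb, acic2, qmaxc) and a
    response that is the stated linear combination. ``model="rbf"``: uniform
    points in the unit cube and a response that is a known mixture of
    Gaussian bumps of the given ``width``. Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)

    if model == "linear":
        coefficients = dict(
            _DEFAULT_LINEAR_COEFFICIENTS if coefficients is None else coefficients
        )
        names = [k for k in coefficients if k != "intercept"]
        cols = {}
        for name in names:
            if name == "ntb":
                cols[name] = rng.integers(0, 3, size=n).astype(float)
            elif name == "qmaxc":
                cols[name] = rng.uniform(0.02, 0.12, size=n)
            else:
                cols[name] = rng.uniform(1.5, 4.5, size=n)
        X = pd.DataFrame(cols)
        y = coefficients.get("intercept", 0.0) + sum(
            coefficients[name] * X[name].to_numpy() for name in names
        )
        y = y + rng.normal(0.0, noise_sd, size=n)
        return SyntheticDataset(X, y, "linear", coefficients, None, None, None,
                                noise_sd, seed)

    if model == "rbf":
        centers = _DEFAULT_RBF_CENTERS if centers is None else np.asarray(centers, float)
        weights = _DEFAULT_RBF_WEIGHTS if weights is None else np.asarray(weights, float)
        if width <= 0:
            raise ValidationError(f"width must be > 0, got {width}")
        if len(weights) != len(centers):
            raise ValidationError("one weight per center required")
        p = centers.shape[1]
        Xv = rng.uniform(0.0, 1.0, size=(n, p))
        d2 = ((Xv[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        y = (np.exp(-d2 / width**2) @ weights) + rng.normal(0.0, noise_sd, size=n)
        X = pd.DataFrame(Xv, columns=[f"x{i + 1}" for i in range(p)])
        return SyntheticDataset(X, y, "rbf", None, centers, weights, width,
                                noise_sd, seed)

    raise ValidationError(f"unknown synthetic model {model!r}; use 'linear' or 'rbf'")
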