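"""Improved artificial immune network (IAIN) classifier.

A clonal-selection prototype learner.  Training samples act as *antigens*
(label + feature vector in [0, 1]); training grows a network of
*antibodies* — prototypes with a label, a center vector and a recognition
radius — by iterating

1. pre-selection: pick the unrecognized antigen covering the most
   unrecognized same-label antigens within its candidate radius;
2. cloning: copy it ``n_clones`` times;
3. mutation: perturb each clone with per-feature Gaussian noise;
4. adaptive antibody calculation: among the original and its mutants, commit
   the candidate recognizing the most unrecognized same-label antigens;
5. reorganization: once every antigen is recognized, prune antibodies whose
   covered antigen set is contained in the union covered by the rest.

The recognition radius of a candidate center is the distance to the nearest
antigen of a *different* label minus a small purity margin, so an antibody
never encloses foreign-class training points.

Classification is nearest-antibody by Euclidean distance.  Queries with
missing features are handled by *sub-antibodies*: every antibody center is
restricted to the query's available feature coordinates and distances are
compared on that common restriction, so irregular time series classify
without imputation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist


class UnclassifiableError(ValueError):
    """Raised when a query exposes no available feature at all."""


@dataclass
class IainConfig:
    """Clonal-selection hyperparameters.

    n_clones
        mutated copies generated per pre-selected antigen (the unmutated
        original always competes as well).
    mutation_sigma
        standard deviation of the per-feature Gaussian perturbation, in
        normalized [0, 1] feature units.
    radius_epsilon
        purity margin subtracted from the nearest-other-class distance when
        assigning a recognition radius.
    max_antibodies
        hard cap on committed antibodies (``None`` -> 1000 per class); the
        loop normally stops much earlier, when every antigen is recognized.
    seed
        seed of the single generator driving mutation.
    """

    n_clones: int = 10
    mutation_sigma: float = 0.05
    radius_epsilon: float = 1e-6
    max_antibodies: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 0:
            raise ValueError("n_clones must be >= 0")
        if self.mutation_sigma < 0:
            raise ValueError("mutation_sigma must be >= 0")
        if self.radius_epsilon < 0:
            raise ValueError("radius_epsilon must be >= 0")


@dataclass
class Antibody:
    label: object
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius < 0:
            raise ValueError("radius must be nonnegative")


# ---------------------------------------------------------------------------
# normalization


def normalize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (min, max) bounds over complete training vectors."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty training matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("training vectors must be complete (no missing values)")
    return X.min(axis=0), X.max(axis=0)


def normalize_apply(
    X: np.ndarray, bounds: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Min-max scale to [0, 1] with clipping; NaN (missing) passes through.

    Degenerate features (min == max) map to 0.5.
    """
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    X = np.asarray(X, dtype=float)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (X - lo) / np.where(span > 0, span, 1.0), 0.5)
    out = np.clip(out, 0.0, 1.0)
    out = np.where(np.isnan(X), np.nan, out)
    return out


# ---------------------------------------------------------------------------
# training primitives (all operate on normalized, complete antigen matrices)


def candidate_radius(
    center: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    label: object,
    radius_epsilon: float = 1e-6,
) -> float:
    """Purity-preserving recognition radius for a candidate center.

    Distance to the nearest antigen of a different label, minus the purity
    margin, floored at zero.  With no other-label antigen the radius spans
    the unit-cube diagonal sqrt(n_features).
    """
    center = np.asarray(center, dtype=float)
    other = np.asarray(y) != label
    if not other.any():
        return float(np.sqrt(center.size))
    d = np.linalg.norm(X[other] - center, axis=1)
    return float(max(d.min() - radius_epsilon, 0.0))


def preselect(
    X: np.ndarray,
    y: np.ndarray,
    unrecognized: np.ndarray,
    radius_epsilon: float = 1e-6,
    distances: np.ndarray | None = None,
) -> int:
    """Index of the unrecognized antigen that best represents the rest.

    "Best" = covers the most unrecognized same-label antigens within its own
    candidate radius; ties break to the lowest antigen index.
    """
    unrec_idx = np.flatnonzero(unrecognized)
    if unrec_idx.size == 0:
        raise ValueError("no unrecognized antigens")
    if distances is None:
        distances = cdist(X, X)
    best_i, best_count = -1, -1
    for i in unrec_idx:
        r = candidate_radius(X[i], X, y, y[i], radius_epsilon)
        cover = unrecognized & (y == y[i]) & (distances[i] <= r)
        count = int(cover.sum())
        if count > best_count:
            best_i, best_count = int(i), count
    return best_i


def clone_and_mutate(
    antigen: np.ndarray, config: IainConfig, rng: np.random.Generator
) -> np.ndarray:
    """The unmutated original plus ``n_clones`` Gaussian-perturbed copies.

    Row 0 is always the original; all entries are clipped to [0, 1].
    """
    antigen = np.asarray(antigen, dtype=float)
    clones = antigen + rng.normal(
        0.0, config.mutation_sigma, size=(config.n_clones, antigen.size)
    )
    return np.vstack([antigen[None, :], np.clip(clones, 0.0, 1.0)])


def commit_best_antibody(
    candidates: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    unrecognized: np.ndarray,
    label: object,
    radius_epsilon: float = 1e-6,
) -> tuple[Antibody, np.ndarray]:
    """Commit the candidate recognizing the most unrecognized antigens.

    Each candidate's radius is computed against *all* antigens (purity);
    its score is the number of unrecognized same-label antigens within that
    radius.  Ties resolve to the original (row 0), then candidate order.
    Returns the antibody and the boolean mask of antigens it newly
    recognizes (nonempty: the original always covers itself at distance 0).
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    if candidates.shape[0] == 0:
        raise ValueError("no candidates")
    same = np.asarray(y) == label
    best = None
    for k, center in enumerate(candidates):
        r = candidate_radius(center, X, y, label, radius_epsilon)
        d = np.linalg.norm(X - center, axis=1)
        cover = unrecognized & same & (d <= r)
        count = int(cover.sum())
        if best is None or count > best[0]:
            best = (count, k, center, r, cover)
    _, _, center, radius, cover = best
    return Antibody(label=label, center=center.copy(), radius=radius), cover


# ---------------------------------------------------------------------------
# the fitted network


@dataclass
class AntibodyNetwork:
    """A trained antibody set plus the normalization fitted on training data."""

    antibodies: list[Antibody]
    bounds_min: np.ndarray
    bounds_max: np.ndarray
    feature_names: list[str]
    config: IainConfig = field(default_factory=IainConfig)
    classes_: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bounds_min = np.asarray(self.bounds_min, dtype=float)
        self.bounds_max = np.asarray(self.bounds_max, dtype=float)
        if np.any(self.bounds_min > self.bounds_max):
            raise ValueError("normalization bounds must satisfy min <= max")
        self._centers = (
            np.vstack([ab.center for ab in self.antibodies])
            if self.antibodies
            else np.empty((0, len(self.feature_names)))
        )
        self._radii = np.array([ab.radius for ab in self.antibodies])
        self._labels = [ab.label for ab in self.antibodies]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    # -- classification ------------------------------------------------
    def classify(self, vector: np.ndarray) -> tuple[object, float, bool]:
        """Label a (possibly incomplete) raw feature vector.

        Missing entries are NaN.  The query is normalized with the training
        bounds, every antibody is restricted to the available coordinates
        (its *sub-antibody*), and the nearest sub-antibody's label wins;
        ties go to the earliest-created antibody.  The returned flag
        reports whether the distance fell within that antibody's radius —
        diagnostic only, it never alters the label.
        """
        v = np.asarray(vector, dtype=float)
        if v.shape != (self.n_features,):
            raise ValueError(
                f"query has {v.size} features, network expects {self.n_features}"
            )
        q = normalize_apply(v[None, :], (self.bounds_min, self.bounds_max))[0]
        avail = ~np.isnan(q)
        if not avail.any():
            raise UnclassifiableError("all features missing")
        diffs = self._centers[:, avail] - q[avail]
        d = np.sqrt((diffs * diffs).sum(axis=1))
        k = int(np.argmin(d))  # first minimum = earliest creation order
        return self._labels[k], float(d[k]), bool(d[k] <= self._radii[k])

    def classify_matrix(
        self, X: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Row-wise :meth:`classify`; returns (labels, unclassifiable mask)."""
        X = np.asarray(X, dtype=float)
        labels = np.empty(X.shape[0], dtype=object)
        bad = np.zeros(X.shape[0], dtype=bool)
        for i in range(X.shape[0]):
            try:
                labels[i], _, _ = self.classify(X[i])
            except UnclassifiableError:
                bad[i] = True
                labels[i] = None
        return labels, bad

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "feature_names": self.feature_names,
            "bounds_min": self.bounds_min.tolist(),
            "bounds_max": self.bounds_max.tolist(),
            "classes": list(self.classes_),
            "config": asdict(self.config),
            "antibodies": [
                {
                    "label": ab.label,
                    "center": ab.center.tolist(),
                    "radius": ab.radius,
                }
                for ab in self.antibodies
            ],
        }
        return json.dumps(payload, indent=1)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "AntibodyNetwork":
        payload = json.loads(text)
        return cls(
            antibodies=[
                Antibody(a["label"], np.array(a["center"]), a["radius"])
                for a in payload["antibodies"]
            ],
            bounds_min=np.array(payload["bounds_min"]),
            bounds_max=np.array(payload["bounds_max"]),
            feature_names=payload["feature_names"],
            config=IainConfig(**payload["config"]),
            classes_=payload["classes"],
        )

    @classmethod
    def load(cls, path) -> "AntibodyNetwork":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# training


def train(
    X: np.ndarray,
    y: Sequence,
    config: IainConfig | None = None,
    feature_names: list[str] | None = None,
) -> AntibodyNetwork:
    """Fit an :class:`AntibodyNetwork` on complete labeled vectors.

    Training antigens must be complete; rows with missing entries are a
    caller error (missing values are a classification-time concern only).
    Identical vectors carrying different labels are tolerated with a
    warning — each ends up under a zero-radius antibody of its own label.
    """
    config = config or IainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(list(y), dtype=object)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    n_missing_rows = int((~np.isfinite(X)).any(axis=1).sum())
    if n_missing_rows:
        raise ValueError(
            f"{n_missing_rows} training vectors contain missing values; "
            "IAIN training requires complete antigens"
        )
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]

    bounds = normalize_fit(X)
    Z = normalize_apply(X, bounds)
    n = Z.shape[0]
    classes = sorted(set(y), key=str)
    cap = config.max_antibodies or 1000 * len(classes)

    # conflicting duplicates: same vector, different label
    D = cdist(Z, Z)
    dup = (D <= 0) & (y[:, None] != y[None, :])
    if dup.any():
        warnings.warn(
            "identical training vectors with conflicting labels; both kept "
            "as zero-radius antibodies",
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    unrecognized = np.ones(n, dtype=bool)
    antibodies: list[Antibody] = []
    coverage: list[np.ndarray] = []  # same-label antigens inside each radius

    while unrecognized.any() and len(antibodies) < cap:
        i = preselect(Z, y, unrecognized, config.radius_epsilon, distances=D)
        candidates = clone_and_mutate(Z[i], config, rng)
        antibody, newly = commit_best_antibody(
            candidates, Z, y, unrecognized, y[i], config.radius_epsilon
        )
        d = np.linalg.norm(Z - antibody.center, axis=1)
        coverage.append((y == antibody.label) & (d <= antibody.radius))
        antibodies.append(antibody)
        unrecognized &= ~newly

    # reorganization: drop antibodies whose covered set is contained in the
    # union covered by the others, scanning in reverse creation order
    keep = list(range(len(antibodies)))
    for k in reversed(range(len(antibodies))):
        others = [j for j in keep if j != k]
        if not others:
            continue
        union = np.zeros(n, dtype=bool)
        for j in others:
            union |= coverage[j]
        if np.all(union[coverage[k]]):
            keep = others
    antibodies = [antibodies[j] for j in keep]

    return AntibodyNetwork(
        antibodies=antibodies,
        bounds_min=bounds[0],
        bounds_max=bounds[1],
        feature_names=feature_names,
        config=config,
        classes_=classes,
    )


def train_cube(cube, labels, config: IainConfig | None = None) -> AntibodyNetwork:
    """Train from a FeatureCube, rejecting pixels with any missing feature.

    Returns the fitted network; the number of rejected (incomplete) training
    pixels is reported via a warning when nonzero.
    """
    labels = np.asarray(labels, dtype=object)
    complete = ~cube.missing.any(axis=1)
    n_rejected = int((~complete).sum())
    if n_rejected:
        warnings.warn(
            f"{n_rejected} training pixels with missing features rejected",
            stacklevel=2,
        )
    return train(
        cube.values[complete],
        labels[complete],
        config=config,
        feature_names=cube.feature_labels(),
    )


def classify_cube(network: AntibodyNetwork, cube) -> tuple[np.ndarray, np.ndarray]:
    """Classify every pixel of a FeatureCube with the trained network.

    Cube features are matched to the network manifest by name; manifest
    features absent from the cube are treated as missing for every pixel.
    Pixels with zero available features are flagged unclassifiable.
    """
    if cube.n_pixels == 0:
        raise ValueError("empty cube")
    cube_names = cube.feature_labels()
    extra = set(cube_names) - set(network.feature_names)
    if extra:
        raise ValueError(f"cube features unknown to the network: {sorted(extra)}")
    col = {name: j for j, name in enumerate(cube_names)}
    X = np.full((cube.n_pixels, network.n_features), np.nan)
    for j, name in enumerate(network.feature_names):
        if name in col:
            src = col[name]
            vals = np.where(cube.missing[:, src], np.nan, cube.values[:, src])
            X[:, j] = vals
    return network.classify_matrix(X)
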