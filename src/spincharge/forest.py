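"""Per-atom, per-spin-state random-forest charge regressors.

The conformation-adaptive charge model fits one ensemble of regression
trees per (atom, spin state): for the 14-heavy-atom heme-O2 model over
three spin states that is 42 independent forests. Each forest holds B
trees grown on bootstrap resamples with m-feature random subsetting at
every node, to purity. The predicted charge of atom i is the mean over
trees,

    q_i = (1/B) sum_j T_j(x_i)

and the reported uncertainty is the population spread of the tree outputs,

    sigma_i = sqrt( (1/B) sum_j (T_j(x_i) - q_i)^2 )

(denominator B, not B-1). The train/test split is frame-wise so that the
three spin responses of one conformation never straddle the split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .descriptors import (
    DescriptorLayout,
    InternalDescriptorDefinition,
    SymmetryFunctionParams,
    build_layout,
    default_internal_definition,
    featurize_frames,
    internal_descriptors_frames,
)
from .errors import (
    AlignmentError,
    ConfigError,
    DataError,
    LayoutError,
    ModelLoadError,
)
from .structure import SPIN_STATES, ChargeTable, Dataset, SpinState, Structure

FORMAT_VERSION = "spincharge-model-1"

MSpec = int | float | Literal["log2", "sqrt", "third", "all"]


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters: B trees, m features per split, split fraction."""

    n_trees: int = 200
    m_spec: MSpec = "third"
    split_fraction: float = 0.5
    seed: int = 0
    min_samples_split: int = 2

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigError("split_fraction must lie strictly in (0, 1)")
        if self.min_samples_split < 2:
            raise ConfigError("min_samples_split must be >= 2")


def resolve_m(m_spec: MSpec, p: int) -> int:
    """Resolve an m specification to an integer feature count in [1, p].

    Integers pass through (capped at p); fractions f in (0,1) give
    ceil(f*p); keywords: log2 -> floor(log2 p), sqrt -> floor(sqrt p),
    third -> ceil(p/3), all -> p. Every mode is floored at 1.
    """
    if p < 1:
        raise ConfigError("p must be >= 1")
    if isinstance(m_spec, bool):
        raise ConfigError("m_spec must be int, fraction, or keyword")
    if isinstance(m_spec, int):
        if m_spec < 1:
            raise ConfigError(f"integer m must be positive, got {m_spec}")
        return min(m_spec, p)
    if isinstance(m_spec, float):
        if not 0.0 < m_spec < 1.0:
            raise ConfigError(f"fractional m must lie in (0, 1), got {m_spec}")
        return max(1, int(np.ceil(m_spec * p)))
    table = {
        "log2": lambda: int(np.floor(np.log2(p))),
        "sqrt": lambda: int(np.floor(np.sqrt(p))),
        "third": lambda: int(np.ceil(p / 3)),
        "all": lambda: p,
    }
    if m_spec not in table:
        raise ConfigError(f"unknown m specification {m_spec!r}")
    return max(1, table[m_spec]())


def parse_m_spec(text: str) -> MSpec:
    """Parse an m specification from text (CLI/config convenience)."""
    if text in ("log2", "sqrt", "third", "all"):
        return text
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        raise ConfigError(f"cannot parse m specification {text!r}") from None


def split_dataset(
    dataset: Dataset, fraction: float = 0.5, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Partition frames uniformly at random into train/test datasets.

    The split is frame-wise: all atoms (and all three spin responses) of a
    frame land on the same side. |train| = round(fraction * N).
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigError("split fraction must lie strictly in (0, 1)")
    n = len(dataset)
    if n < 2:
        raise DataError("need at least 2 frames to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    tr, te = np.sort(order[:n_train]), np.sort(order[n_train:])

    def take(idx):
        return Dataset(
            [dataset.structures[i] for i in idx],
            [dataset.tables[i] for i in idx] if dataset.tables else [],
        )

    return take(tr), take(te)


@dataclass(frozen=True)
class FeaturizerSpec:
    """Featurization metadata persisted with a model.

    scheme 'sf': per-atom symmetry-function vectors (layout + params).
    scheme 'internal': one internal-coordinate vector per frame, shared by
    every atom's model.

    With ``log_compress`` (default for 'sf') the trees are fit on
    log-transformed symmetry-function values. Tree splits are invariant
    under strictly monotone per-feature transforms, so this changes
    nothing mathematically; it exists because symmetry functions span
    tens of orders of magnitude (Gaussian factors of far pairs) and the
    tree splitter resolves split points on an absolute scale. Internal
    coordinates are O(1)-scaled and are used raw.
    """

    scheme: Literal["sf", "internal"]
    layout: DescriptorLayout | None = None
    sf_params: SymmetryFunctionParams = SymmetryFunctionParams()
    internal_definition: InternalDescriptorDefinition | None = None
    log_compress: bool = True

    #: floor applied before the log; descriptor values are >= 0 and exact
    #: zeros (empty sums) map to log of this floor.
    _LOG_FLOOR = 1e-300

    @staticmethod
    def symmetry_functions(
        composition: dict[str, int],
        params: SymmetryFunctionParams = SymmetryFunctionParams(),
    ) -> "FeaturizerSpec":
        return FeaturizerSpec(
            scheme="sf", layout=build_layout(composition), sf_params=params
        )

    @staticmethod
    def internal(
        definition: InternalDescriptorDefinition | None = None,
    ) -> "FeaturizerSpec":
        return FeaturizerSpec(
            scheme="internal",
            internal_definition=definition or default_internal_definition(),
        )

    @property
    def n_features(self) -> int:
        if self.scheme == "sf":
            return self.layout.size
        return self.internal_definition.size

    def feature_names(self) -> list[str]:
        if self.scheme == "sf":
            return self.layout.component_names()
        return self.internal_definition.component_names()

    def features(self, structures: Sequence[Structure]) -> np.ndarray:
        """Per-frame regression inputs; (n_frames, n_atoms, p) for sf, (n_frames, p) else."""
        if self.scheme == "sf":
            raw = featurize_frames(structures, self.layout, self.sf_params)
            if self.log_compress:
                return np.log(np.maximum(raw, self._LOG_FLOOR))
            return raw
        return internal_descriptors_frames(structures, self.internal_definition)

    def atom_features(
        self, features: np.ndarray, atom_index: int
    ) -> np.ndarray:
        """Feature matrix (n_frames, p) for one atom's regressor."""
        if self.scheme == "sf":
            return features[:, atom_index, :]
        return features


@dataclass
class TrainedChargeModel:
    """Map (atom_index, spin) -> fitted forest, plus featurization metadata."""

    forests: dict[tuple[int, SpinState], RandomForestRegressor]
    featurizer: FeaturizerSpec
    config: ForestConfig
    atom_elements: dict[int, str]
    n_train: int

    @property
    def atom_indices(self) -> list[int]:
        return sorted(self.atom_elements)

    @property
    def n_models(self) -> int:
        return len(self.forests)


@dataclass
class PredictionResult:
    """Ensemble-mean charges and tree-spread uncertainties for one frame."""

    atom_indices: np.ndarray
    q_mean: np.ndarray  # (n_atoms, 3), spin columns in SPIN_STATES order
    q_std: np.ndarray  # (n_atoms, 3)
    frame_id: int = 0

    def mean(self, atom: int, spin: SpinState) -> float:
        row = int(np.nonzero(self.atom_indices == atom)[0][0])
        return float(self.q_mean[row, SPIN_STATES.index(spin)])

    def std(self, atom: int, spin: SpinState) -> float:
        row = int(np.nonzero(self.atom_indices == atom)[0][0])
        return float(self.q_std[row, SPIN_STATES.index(spin)])


def _sub_seed(master: int, atom_index: int, spin: SpinState) -> int:
    """Deterministic, order-independent per-model seed below 2^31."""
    ss = np.random.SeedSequence(
        entropy=master, spawn_key=(atom_index, SPIN_STATES.index(spin))
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def train_forest(
    X: np.ndarray, y: np.ndarray, config: ForestConfig, seed: int | None = None
) -> RandomForestRegressor:
    """Fit one ensemble: B bootstrap trees, m-feature subsetting, grown to purity."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DataError("X and y row counts differ")
    if X.shape[0] < 1:
        raise DataError("empty training set")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DataError("NaN or infinite value in training data")
    m = resolve_m(config.m_spec, X.shape[1])
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=m,
        min_samples_split=config.min_samples_split,
        bootstrap=True,
        random_state=config.seed if seed is None else seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def _check_alignment(dataset: Dataset) -> None:
    if not dataset.tables:
        raise AlignmentError("dataset carries no charge tables")
    struct_ids = [s.frame_id for s in dataset.structures]
    table_ids = [t.frame_id for t in dataset.tables]
    if struct_ids != table_ids:
        missing = sorted(set(struct_ids) ^ set(table_ids))
        raise AlignmentError(
            f"structures and charge tables disagree on frames; "
            f"unmatched frame_ids: {missing[:20]}"
        )
    first = dataset.tables[0].atom_index
    for t in dataset.tables[1:]:
        if not np.array_equal(t.atom_index, first):
            raise AlignmentError(
                f"frame {t.frame_id} covers different atom indices"
            )


def train_all(
    dataset: Dataset,
    featurizer: FeaturizerSpec,
    config: ForestConfig = ForestConfig(),
) -> TrainedChargeModel:
    """Train one forest per (atom, spin) on aligned structures + charges.

    Features are computed once per frame and shared across each atom's
    three spin models. Per-model seeds fan out deterministically from
    ``config.seed`` so training order does not matter.
    """
    _check_alignment(dataset)
    feats = featurizer.features(dataset.structures)
    atom_idx = dataset.tables[0].atom_index
    charges = np.stack([t.charges for t in dataset.tables])  # (F, A, 3)
    forests: dict[tuple[int, SpinState], RandomForestRegressor] = {}
    for a_pos, atom in enumerate(atom_idx):
        X = featurizer.atom_features(feats, int(atom))
        for s_i, spin in enumerate(SPIN_STATES):
            y = charges[:, a_pos, s_i]
            forests[(int(atom), spin)] = train_forest(
                X, y, config, seed=_sub_seed(config.seed, int(atom), spin)
            )
    elements = {
        int(i): e for i, e in zip(atom_idx, dataset.tables[0].elements)
    }
    return TrainedChargeModel(
        forests=forests,
        featurizer=featurizer,
        config=config,
        atom_elements=elements,
        n_train=len(dataset),
    )


def _check_structure(model: TrainedChargeModel, structure: Structure) -> None:
    fz = model.featurizer
    if fz.scheme == "sf" and not set(structure.elements) <= set(
        fz.layout.element_order
    ):
        raise LayoutError("structure contains elements outside the model layout")
    for atom, elem in model.atom_elements.items():
        if atom >= structure.n_atoms:
            raise LayoutError(
                f"model expects atom index {atom}, structure has "
                f"{structure.n_atoms} atoms"
            )
        if structure.elements[atom] != elem:
            raise LayoutError(
                f"atom {atom} is {structure.elements[atom]}, model was "
                f"trained on {elem}"
            )


def tree_outputs(
    model: TrainedChargeModel,
    structure: Structure,
    atom: int,
    spin: SpinState,
) -> np.ndarray:
    """Individual tree predictions T_j(x) for one (atom, spin); length B."""
    _check_structure(model, structure)
    feats = model.featurizer.features([structure])
    x = model.featurizer.atom_features(feats, atom)  # (1, p)
    forest = model.forests[(atom, spin)]
    return np.array([t.predict(x)[0] for t in forest.estimators_])


def predict(model: TrainedChargeModel, structure: Structure) -> PredictionResult:
    """Ensemble-mean charge and denominator-B tree spread for every modeled atom."""
    _check_structure(model, structure)
    feats = model.featurizer.features([structure])
    atoms = model.atom_indices
    q_mean = np.zeros((len(atoms), 3))
    q_std = np.zeros((len(atoms), 3))
    for r, atom in enumerate(atoms):
        x = model.featurizer.atom_features(feats, atom)
        for s_i, spin in enumerate(SPIN_STATES):
            forest = model.forests[(atom, spin)]
            preds = np.array([t.predict(x)[0] for t in forest.estimators_])
            q_mean[r, s_i] = preds.mean()
            q_std[r, s_i] = np.sqrt(np.mean((preds - preds.mean()) ** 2))
    return PredictionResult(
        atom_indices=np.array(atoms),
        q_mean=q_mean,
        q_std=q_std,
        frame_id=structure.frame_id,
    )


def predict_frames(
    model: TrainedChargeModel, structures: Sequence[Structure]
) -> list[PredictionResult]:
    """Predict every frame; features are computed once per frame.

    Faster batch path than calling :func:`predict` per frame: each forest
    evaluates all frames in one pass. Identical results.
    """
    for s in structures:
        _check_structure(model, s)
    feats = model.featurizer.features(structures)
    atoms = model.atom_indices
    n_f = len(structures)
    q_mean = np.zeros((n_f, len(atoms), 3))
    q_std = np.zeros((n_f, len(atoms), 3))
    for r, atom in enumerate(atoms):
        X = model.featurizer.atom_features(feats, atom)  # (F, p)
        for s_i, spin in enumerate(SPIN_STATES):
            forest = model.forests[(atom, spin)]
            all_preds = np.stack(
                [t.predict(X) for t in forest.estimators_]
            )  # (B, F)
            q_mean[:, r, s_i] = all_preds.mean(axis=0)
            q_std[:, r, s_i] = np.sqrt(
                np.mean((all_preds - all_preds.mean(axis=0)) ** 2, axis=0)
            )
    return [
        PredictionResult(
            atom_indices=np.array(atoms),
            q_mean=q_mean[f],
            q_std=q_std[f],
            frame_id=structures[f].frame_id,
        )
        for f in range(n_f)
    ]


def save_model(model: TrainedChargeModel, path) -> None:
    """Persist a model as a single compressed archive with a version tag."""
    payload = {
        "format_version": FORMAT_VERSION,
        "featurizer": model.featurizer,
        "config": model.config,
        "atom_elements": model.atom_elements,
        "n_train": model.n_train,
        "forests": {
            (a, s.name): f for (a, s), f in model.forests.items()
        },
    }
    joblib.dump(payload, path, compress=3)


def load_model(path) -> TrainedChargeModel:
    """Load a model archive; unknown versions or truncated files error."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelLoadError(f"{path}: unreadable model archive: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelLoadError(f"{path}: not a spincharge model archive")
    if payload["format_version"] != FORMAT_VERSION:
        raise ModelLoadError(
            f"{path}: unsupported format version {payload['format_version']!r}"
        )
    forests = {
        (a, SpinState[s]): f for (a, s), f in payload["forests"].items()
    }
    return TrainedChargeModel(
        forests=forests,
        featurizer=payload["featurizer"],
        config=payload["config"],
        atom_elements=payload["atom_elements"],
        n_train=payload["n_train"],
    )
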