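"""Virtual-blend purity modelling and juice-authenticity decision rules.

Adulteration of orange juice with mandarin juice (and grapefruit juice with
pomelo juice) is modelled by regressing the purity of virtual blends —
purity-weighted averages of pure-juice marker profiles — on a small set of
scenario-specific marker compounds:

* orange vs mandarin: isosinensetin (15), sinensetin (17), tangeretin (26);
* grapefruit vs Shatianyou-group (SG) pomelo: meranzin (13),
  3,5,6,7,8,3',4'-heptamethoxyflavone (24), osthole (31),
  6',7'-epoxybergamottin (33), bergamottin (36);
* grapefruit vs Wendan-group (WG) pomelo: bergaptol (6), isomeranzin (14),
  6',7'-dihydroxybergamottin (25).

A PLS1 model selected by full cross-validation predicts the purity (PP, %)
of an unknown sample; PP is reported unclipped (values beyond [0, 100] are
meaningful model output). The published decision thresholds then label the
sample authentic, indeterminate or fraudulent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chemometrics import PLS1Regression, cross_validate
from .profiles import ProfileMatrix, SampleMeta


class AuthenticityError(ValueError):
    pass


SCENARIOS = ("orange_vs_mandarin", "grapefruit_vs_SG", "grapefruit_vs_WG")

# Marker variables per scenario, as catalog compound ids.
SCENARIO_VARIABLES: dict[str, tuple[str, ...]] = {
    "orange_vs_mandarin": ("15", "17", "26"),
    "grapefruit_vs_SG": ("13", "24", "31", "33", "36"),
    "grapefruit_vs_WG": ("6", "14", "25"),
}

SCENARIO_MAIN_SPECIES = {
    "orange_vs_mandarin": "orange",
    "grapefruit_vs_SG": "grapefruit",
    "grapefruit_vs_WG": "grapefruit",
}


@dataclass(frozen=True)
class DecisionRule:
    """Published authenticity thresholds on predicted purity (%, PP)."""

    authentic_min: float
    fraud_max: float

    def __post_init__(self) -> None:
        if not self.fraud_max < self.authentic_min:
            raise AuthenticityError("fraud_max must be below authentic_min")


# PP >= authentic_min -> authentic; PP < fraud_max -> fraudulent.
DECISION_RULES: dict[str, DecisionRule] = {
    "orange_vs_mandarin": DecisionRule(authentic_min=94.0, fraud_max=82.0),
    "grapefruit_vs_SG": DecisionRule(authentic_min=94.0, fraud_max=85.0),
    "grapefruit_vs_WG": DecisionRule(authentic_min=95.0, fraud_max=87.0),
}


def default_blend_spec(scenario: str) -> BlendSpec:
    """Published training design per scenario.

    Orange vs mandarin trains on purities 95/90/80 plus pure orange (100)
    and pure mandarin (0); the grapefruit scenarios use levels 100/90/80
    with no pure-adulterant rows.
    """
    if scenario == "orange_vs_mandarin":
        return BlendSpec(
            main_species="orange", adulterant="mandarin",
            purity_levels=(95.0, 90.0, 80.0),
            include_pure_main=True, include_pure_adulterant=True,
        )
    if scenario in ("grapefruit_vs_SG", "grapefruit_vs_WG"):
        return BlendSpec(
            main_species="grapefruit",
            adulterant="pomelo_SG" if scenario.endswith("SG") else "pomelo_WG",
            purity_levels=(90.0, 80.0),
            include_pure_main=True, include_pure_adulterant=False,
        )
    raise AuthenticityError(f"unknown scenario {scenario!r}")


def classify_label(pp: float, rule: DecisionRule) -> str:
    """Authenticity verdict from predicted purity: monotone in PP."""
    if pp >= rule.authentic_min:
        return "authentic"
    if pp < rule.fraud_max:
        return "fraudulent"
    return "indeterminate"


@dataclass(frozen=True)
class BlendSpec:
    """Virtual blend design: purity levels and pure-juice inclusion flags."""

    main_species: str
    adulterant: str
    purity_levels: tuple[float, ...] = (95.0, 90.0, 80.0)
    include_pure_main: bool = True
    include_pure_adulterant: bool = False

    def __post_init__(self) -> None:
        levels = self.purity_levels
        if len(set(levels)) != len(levels):
            raise AuthenticityError("purity levels must be distinct")
        if any(not 0 <= p <= 100 for p in levels):
            raise AuthenticityError("purity levels must lie in [0, 100]")


@dataclass(frozen=True)
class BlendSet:
    """Blend profiles with reference purities and full provenance."""

    matrix: ProfileMatrix
    y: np.ndarray  # purity %, per row
    provenance: tuple[tuple[Optional[str], Optional[str], float], ...]

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.shape[0] != self.matrix.n_samples:
            raise AuthenticityError("y length must match matrix rows")
        object.__setattr__(self, "y", y)


def generate_blends(
    main_profiles: ProfileMatrix,
    adulterant_profiles: ProfileMatrix,
    spec: BlendSpec,
) -> BlendSet:
    """Exhaustive virtual blends of every main × adulterant profile pair.

    Each blended row at purity p is exactly p/100·main + (1−p/100)·adulterant
    elementwise. Pure main juices enter with y = 100 and pure adulterants
    with y = 0 according to the spec flags.
    """
    if main_profiles.n_samples == 0 or adulterant_profiles.n_samples == 0:
        raise AuthenticityError("profile sets must be nonempty")
    if main_profiles.columns != adulterant_profiles.columns:
        raise AuthenticityError("main and adulterant variable columns differ")
    rows: list[np.ndarray] = []
    metas: list[SampleMeta] = []
    y: list[float] = []
    provenance: list[tuple[Optional[str], Optional[str], float]] = []
    counter = 0
    for p in spec.purity_levels:
        frac = p / 100.0
        for i, m_meta in enumerate(main_profiles.metas):
            for j, a_meta in enumerate(adulterant_profiles.metas):
                rows.append(frac * main_profiles.values[i]
                            + (1.0 - frac) * adulterant_profiles.values[j])
                metas.append(SampleMeta(
                    sample_id=f"blend_{counter}",
                    species=m_meta.species,
                    cultivar=f"{m_meta.cultivar}+{a_meta.cultivar}",
                    region="blend", harvest_year=0,
                ))
                y.append(p)
                provenance.append((m_meta.sample_id, a_meta.sample_id, p))
                counter += 1
    if spec.include_pure_main:
        for i, meta in enumerate(main_profiles.metas):
            rows.append(main_profiles.values[i].copy())
            metas.append(SampleMeta(
                sample_id=f"pure_main_{counter}", species=meta.species,
                cultivar=meta.cultivar, region=meta.region,
                harvest_year=meta.harvest_year, subgroup=meta.subgroup,
            ))
            y.append(100.0)
            provenance.append((meta.sample_id, None, 100.0))
            counter += 1
    if spec.include_pure_adulterant:
        for j, meta in enumerate(adulterant_profiles.metas):
            rows.append(adulterant_profiles.values[j].copy())
            metas.append(SampleMeta(
                sample_id=f"pure_adulterant_{counter}", species=meta.species,
                cultivar=meta.cultivar, region=meta.region,
                harvest_year=meta.harvest_year, subgroup=meta.subgroup,
            ))
            y.append(0.0)
            provenance.append((None, meta.sample_id, 0.0))
            counter += 1
    matrix = ProfileMatrix(
        metas=tuple(metas), columns=main_profiles.columns,
        values=np.vstack(rows), value_kind=dict(main_profiles.value_kind),
    )
    return BlendSet(matrix=matrix, y=np.array(y), provenance=tuple(provenance))


class PurityModel(PLS1Regression):
    """Scenario-bound PLS purity predictor with its decision rule attached.

    A scikit-learn style regressor: ``fit`` takes the marker-variable block
    and reference purities, performs full cross-validation up to
    ``max_components`` latent variables, refits at the suggested count and
    stores the RMSECV curve. ``predict`` returns unclipped predicted purity
    (PP, %).
    """

    def __init__(self, scenario: str = "orange_vs_mandarin",
                 max_components: int = 3, scale: bool = True,
                 segmentation: str | int = "loo"):
        super().__init__(n_components=max_components, scale=scale)
        self.scenario = scenario
        self.max_components = max_components
        self.segmentation = segmentation

    def fit(self, X, y):
        if self.scenario not in SCENARIOS:
            raise AuthenticityError(f"unknown scenario {self.scenario!r}")
        X = np.asarray(X, dtype=float)
        cv = cross_validate(X, y, self.max_components,
                            segmentation=self.segmentation)
        self.cv_ = cv
        self.rmsecv_ = float(cv.rmsecv[cv.suggested_components - 1])
        self.rmsecv_curve_ = cv.rmsecv
        self.n_components = cv.suggested_components
        super().fit(X, y)
        self.decision_rule_ = DECISION_RULES[self.scenario]
        self.variables_ = SCENARIO_VARIABLES[self.scenario]
        return self

    def classify(self, pp: float) -> str:
        return classify_label(pp, self.decision_rule_)


def train_purity_model(
    blends: BlendSet,
    scenario: str,
    max_components: int = 3,
    variables: Optional[Sequence[str]] = None,
) -> PurityModel:
    """Fit a purity model on a blend set restricted to the scenario markers."""
    variables = tuple(variables or SCENARIO_VARIABLES[scenario])
    known = set(SCENARIO_VARIABLES[scenario])
    extra = set(variables) - known
    if extra:
        raise AuthenticityError(
            f"variables {sorted(extra)} are not part of scenario {scenario}"
        )
    missing = [v for v in variables if v not in blends.matrix.columns]
    if missing:
        raise AuthenticityError(f"blend set lacks marker columns: {missing}")
    X = blends.matrix.select(variables).values
    model = PurityModel(scenario=scenario, max_components=max_components)
    model.fit(X, blends.y)
    return model


def predict_purity(model: PurityModel, sample: np.ndarray | Sequence[float]) -> float:
    """Unclipped predicted purity (%) for one sample row of marker values."""
    row = np.asarray(sample, dtype=float).ravel()
    if row.shape[0] != model.n_features_in_:
        raise AuthenticityError(
            f"sample has {row.shape[0]} variables, model expects "
            f"{model.n_features_in_}"
        )
    return float(model.predict(row[None, :])[0])


@dataclass(frozen=True)
class ModelEvaluation:
    rmsep: float
    r_squared: Optional[float]  # Pearson R² of PP vs reference purity
    pp_ranges: dict[float, tuple[float, float]]  # purity level -> (min, max) PP
    predictions: np.ndarray = field(repr=False, default=None)


def evaluate_model(model: PurityModel, test: BlendSet) -> ModelEvaluation:
    """RMSEP, Pearson R² and per-level PP ranges on an external test set."""
    if test.matrix.n_samples == 0:
        raise AuthenticityError("test set is empty")
    X = test.matrix.select(list(model.variables_)).values \
        if set(model.variables_) <= set(test.matrix.columns) \
        else test.matrix.values
    pp = model.predict(X)
    resid = pp - test.y
    rmsep = float(np.sqrt(np.mean(resid ** 2)))
    r2: Optional[float] = None
    if test.matrix.n_samples >= 2 and np.std(test.y) > 0 and np.std(pp) > 0:
        r = float(np.corrcoef(pp, test.y)[0, 1])
        r2 = r * r
    ranges: dict[float, tuple[float, float]] = {}
    for level in np.unique(test.y):
        sel = test.y == level
        ranges[float(level)] = (float(pp[sel].min()), float(pp[sel].max()))
    return ModelEvaluation(rmsep=rmsep, r_squared=r2, pp_ranges=ranges,
                           predictions=pp)


def classify_grapefruit_conservative(pp_sg: float, pp_wg: float) -> str:
    """Worst-case verdict when the pomelo subgroup is not declared.

    Both subgroup models are run and the more pessimistic label is kept, to
    avoid false authentication.
    """
    order = {"authentic": 0, "indeterminate": 1, "fraudulent": 2}
    label_sg = classify_label(pp_sg, DECISION_RULES["grapefruit_vs_SG"])
    label_wg = classify_label(pp_wg, DECISION_RULES["grapefruit_vs_WG"])
    return max((label_sg, label_wg), key=lambda lab: order[lab])
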