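"""Synthetic juice profiles, anchor ladders and chromatogram peak tables.

The generator emulates the species structure of citrus-juice OHA profiles:

* per-species "hot spot" compounds (the methoxyflavone-rich orange/mandarin
  patterns and the coumarin/furanocoumarin-rich grapefruit/pomelo patterns);
* total-OHA scales per species — sweet orange juice below 5 mg/L, mandarin
  5–10 mg/L, grapefruit and pomelo 5–100 mg/L;
* cultivar-to-cultivar lognormal variability with a configurable
  coefficient of variation (default 0.25).

Per-compound concentration scales beyond the species totals are not
published; the template magnitudes are synthetic, self-declared values that
reproduce the qualitative marker structure, not measurements.

A sampled profile can be inverted into a synthetic chromatogram peak table
(one peak per detected compound, plus the psoralen internal standard), so
the identification → quantitation → profiling pipeline is testable end to
end without any instrument data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _tables
from .catalog import CompoundRecord, catalog_index
from .peaks import AnchorSeries, ChromatogramPeak
from .profiles import ProfileMatrix, SampleMeta
from .spectra import synthetic_emission_trace, synthetic_uv_trace


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_cultivars: int = 20
    replicates: int = 1
    cv: float = 0.25  # cultivar-level coefficient of variation
    rt_jitter_sd: float = 0.0  # minutes
    detector_noise_sd: float = 0.0  # area units
    is_drift: float = 1.0  # observed/nominal internal-standard response

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise SimulationError("cv must be positive")
        if self.n_cultivars < 1 or self.replicates < 1:
            raise SimulationError("need at least one cultivar and replicate")


@dataclass(frozen=True)
class SpeciesTemplate:
    """Mean concentration pattern (mg/L) of one juice species/subgroup."""

    species: str
    subgroup: str
    means: dict[str, float]  # compound id -> mean mg/L
    hot_spots: frozenset[str]
    total_range: tuple[float, float]

    def __post_init__(self) -> None:
        total = sum(self.means.values())
        lo, hi = self.total_range
        if not lo <= total <= hi:
            raise SimulationError(
                f"{self.species}/{self.subgroup}: expected total {total:.2f} "
                f"mg/L outside the species range [{lo}, {hi}]"
            )


def default_templates() -> list[SpeciesTemplate]:
    """The five study conditions: orange, mandarin, grapefruit, pomelo SG/WG.

    Hot spots follow the species profiles: orange methoxyflavones 20, 17, 23,
    24 (sinensetin 17 high, isosinensetin 15 and tangeretin 26 low); mandarin
    24, 22, 26, 27, 15, 21, 30; grapefruit rich in coumarins/FCs 18–31 plus
    the SG-scenario markers heptamethoxyflavone (24), osthole (31),
    6',7'-epoxybergamottin (33) and bergamottin (36); SG pomelo elevated in
    meranzin (13) with traces of MFs 23–27; WG pomelo elevated in the
    acid-stable markers bergaptol (6), isomeranzin (14) and
    6',7'-dihydroxybergamottin (25).
    """
    orange = {
        "17": 1.2, "20": 0.9, "23": 0.7, "24": 0.6,
        "15": 0.02, "26": 0.02, "22": 0.1, "21": 0.05, "27": 0.03,
        "30": 0.0, "1": 0.1, "2": 0.05, "V": 0.15, "VI": 0.12,
    }
    mandarin = {
        "24": 1.8, "22": 1.4, "26": 1.2, "27": 0.9, "15": 1.0, "21": 0.8,
        "30": 0.6, "17": 0.08, "20": 0.05, "23": 0.1, "1": 0.1, "2": 0.05,
    }
    grapefruit = {
        # coumarins / FCs 18-31 dominate, plus the SG-model markers
        "18": 2.5, "19": 1.5, "25": 3.5, "28": 1.8, "31": 3.0, "13": 0.8,
        "24": 1.6, "33": 2.8, "36": 6.0, "6": 1.0, "14": 0.8, "5": 1.5,
        "10": 2.0, "32": 1.5, "35": 2.5, "11": 1.0, "XI": 0.9,
        "22": 0.6, "23": 0.5, "26": 0.4, "27": 0.3,
    }
    pomelo_sg = {
        # high-pH juice keeps the epoxides: meranzin high, MFs 23-27 trace
        "13": 6.0, "5": 2.5, "35": 3.0, "19": 1.2, "36": 1.5, "33": 0.7,
        "24": 0.15, "31": 0.5, "23": 0.08, "25": 1.2, "6": 0.8, "14": 0.6,
        "26": 0.05, "27": 0.04, "10": 1.0, "18": 0.8,
    }
    pomelo_wg = {
        # acid-stable markers dominate the sour Wendan juices
        "6": 5.0, "14": 4.0, "25": 9.0, "13": 0.2, "5": 1.0, "35": 2.0,
        "19": 0.8, "36": 1.8, "33": 0.8, "31": 0.6, "24": 0.05, "10": 1.2,
        "18": 1.0, "32": 0.8,
    }
    return [
        SpeciesTemplate("orange", "none", orange,
                        frozenset({"20", "17", "23", "24"}), (0.0, 5.0)),
        SpeciesTemplate("mandarin", "none", mandarin,
                        frozenset({"24", "22", "26", "27", "15", "21", "30"}),
                        (5.0, 10.0)),
        SpeciesTemplate("grapefruit", "none", grapefruit,
                        frozenset({"36", "33", "31", "24", "25"}), (5.0, 100.0)),
        SpeciesTemplate("pomelo", "SG", pomelo_sg,
                        frozenset({"13"}), (5.0, 100.0)),
        SpeciesTemplate("pomelo", "WG", pomelo_wg,
                        frozenset({"6", "14", "25"}), (5.0, 100.0)),
    ]


def get_template(species: str, subgroup: str = "none") -> SpeciesTemplate:
    for tpl in default_templates():
        if tpl.species == species and tpl.subgroup == subgroup:
            return tpl
    raise SimulationError(f"no template for {species}/{subgroup}")


def sample_profiles(
    template: SpeciesTemplate,
    config: SimConfig,
    columns: Optional[Sequence[str]] = None,
    cultivar_offset: int = 0,
) -> ProfileMatrix:
    """Lognormal cultivar profiles around the template means.

    Each compound is drawn independently with median equal to the template
    mean and sdlog = sqrt(ln(1 + cv²)), so the empirical coefficient of
    variation matches ``config.cv``. Replicate rows within a cultivar share
    the cultivar draw (within-cultivar noise uses cv/5).
    """
    rng = np.random.default_rng(config.seed)
    cols = tuple(columns) if columns is not None else tuple(
        sorted(template.means, key=_column_sort_key)
    )
    means = np.array([template.means.get(c, 0.0) for c in cols])
    sdlog = math.sqrt(math.log(1.0 + config.cv ** 2))
    rep_sdlog = math.sqrt(math.log(1.0 + (config.cv / 5.0) ** 2))
    metas: list[SampleMeta] = []
    rows: list[np.ndarray] = []
    tag = template.species if template.subgroup == "none" \
        else f"{template.species}_{template.subgroup}"
    for c in range(config.n_cultivars):
        factors = np.exp(rng.normal(0.0, sdlog, size=means.size))
        cultivar_profile = means * factors
        for r in range(config.replicates):
            if config.replicates > 1:
                noise = np.exp(rng.normal(0.0, rep_sdlog, size=means.size))
            else:
                noise = 1.0
            rows.append(cultivar_profile * noise)
            metas.append(SampleMeta(
                sample_id=f"{tag}_c{c + cultivar_offset}_r{r}",
                species=template.species,
                subgroup=template.subgroup,
                cultivar=f"{tag}_cv{c + cultivar_offset}",
                region="synthetic",
                harvest_year=2020 + r,
            ))
    return ProfileMatrix(
        metas=tuple(metas), columns=cols, values=np.vstack(rows),
        value_kind={c: ("area" if not c.isdigit() else "concentration")
                    for c in cols},
    )


def _column_sort_key(label: str):
    return (0, int(label)) if label.isdigit() else (1, label)


DEFAULT_ANCHOR_TIMES = (
    (8, 8.487), (9, 16.945), (10, 26.177), (11, 36.315),
    (12, 38.70), (13, 42.04), (14, 48.04),
)


def synth_anchor_series(config: Optional[SimConfig] = None) -> AnchorSeries:
    """C8–C14 alkylarylketone ladder over the elution window.

    The default times are a synthetic ladder consistent with the candidate
    compounds' retention indices. With ``rt_jitter_sd`` set, seeded jitter is
    applied while preserving strict monotonicity.
    """
    times = [(c, t) for c, t in DEFAULT_ANCHOR_TIMES]
    if config is not None and config.rt_jitter_sd > 0:
        rng = np.random.default_rng(config.seed + 7)
        jittered = []
        prev = 0.0
        for c, t in times:
            t_j = t + rng.normal(0.0, config.rt_jitter_sd)
            t_j = max(t_j, prev + 0.05)
            jittered.append((c, t_j))
            prev = t_j
        times = jittered
    return AnchorSeries(ketones=tuple(times))


def synth_chromatogram(
    profile_row: dict[str, float],
    catalog: Sequence[CompoundRecord],
    anchors: AnchorSeries,
    config: SimConfig,
) -> list[ChromatogramPeak]:
    """Invert the quantitation model: one synthetic peak per detected compound.

    Areas on the quantitation channel are concentration × 9 (the SPE
    concentration factor) × calibration slope, plus optional detector noise;
    fluorescence heights realize the catalog monitor pair and ratio; spectra
    come from the synthetic library traces. A psoralen internal-standard
    peak is injected at nominal response × ``is_drift``.
    """
    rng = np.random.default_rng(config.seed + 13)
    index = catalog_index(catalog)
    peaks: list[ChromatogramPeak] = []
    for compound_id, conc in profile_row.items():
        if conc <= 0:
            continue
        record = index.get(compound_id)
        if record is None or record.retention_time is None:
            continue
        rt = record.retention_time
        if config.rt_jitter_sd > 0:
            rt = max(rt + rng.normal(0.0, config.rt_jitter_sd), 0.01)
        detector, wavelength = record.quant_channel
        areas: dict[int, float] = {}
        heights: dict[int, float] = {}
        # is_drift models a detector-wide response drift: every response,
        # including the internal standard's, scales by the same factor, so
        # the nominal/observed IS correction cancels it at quantitation.
        if record.uv_calibration is not None:
            area = conc * 9.0 * record.uv_calibration.slope * config.is_drift
            if config.detector_noise_sd > 0:
                area = max(area + rng.normal(0.0, config.detector_noise_sd), 0.0)
            areas[wavelength if detector == "UV" else 330] = area
        else:
            # candidate compounds: report an arbitrary-unit response area
            areas[wavelength] = conc * config.is_drift
        em_trace = None
        if record.fluoresces and record.fl_monitor_pair is not None:
            base = conc * 9.0 * config.is_drift * (
                record.fl_calibration.slope if record.fl_calibration else 1.0
            )
            hi_nm, sec_nm = record.fl_monitor_pair
            third = [nm for nm in (400, 450, 500) if nm not in (hi_nm, sec_nm)][0]
            heights[hi_nm] = base
            heights[sec_nm] = base / record.fl_ratio
            heights[third] = base / (record.fl_ratio * 4.0)
            em_trace = synthetic_emission_trace(record.emission_max)
        peaks.append(ChromatogramPeak(
            rt=rt,
            uv_spectrum=synthetic_uv_trace(record.uv_maxima, record.family),
            em_spectrum=em_trace,
            heights=heights,
            areas=areas,
        ))
    is_response = _tables.IS_NOMINAL_RESPONSE * config.is_drift
    peaks.append(ChromatogramPeak(
        rt=_tables.IS_RT_MIN,
        uv_spectrum=None,
        em_spectrum=None,
        heights={},
        areas={250: is_response},
    ))
    return sorted(peaks, key=lambda p: p.rt)


def extract_is_ratio(peaks: Sequence[ChromatogramPeak],
                     rt_window: float = 0.3) -> float:
    """Nominal/observed psoralen response ratio from a peak table."""
    for peak in peaks:
        if abs(peak.rt - _tables.IS_RT_MIN) <= rt_window and 250 in peak.areas:
            observed = peak.areas[250]
            if observed > 0:
                return _tables.IS_NOMINAL_RESPONSE / observed
    raise SimulationError("internal-standard peak not found")


# ---------------------------------------------------------------------------
# Scenario-level simulation


def scenario_species(scenario: str) -> tuple[tuple[str, str], tuple[str, str]]:
    """(main, adulterant) (species, subgroup) pairs for a scenario."""
    if scenario == "orange_vs_mandarin":
        return ("orange", "none"), ("mandarin", "none")
    if scenario == "grapefruit_vs_SG":
        return ("grapefruit", "none"), ("pomelo", "SG")
    if scenario == "grapefruit_vs_WG":
        return ("grapefruit", "none"), ("pomelo", "WG")
    raise SimulationError(f"unknown scenario {scenario!r}")


def simulate_scenario(
    scenario: str,
    seed: int,
    n_train_cultivars: int = 20,
    n_test_cultivars: int = 10,
    cv: float = 0.25,
    purity_levels: Sequence[float] = (95.0, 90.0, 80.0),
    include_pure_adulterant: bool = True,
):
    """Cultivar-disjoint training and external-test blend sets for a scenario.

    Training blends use the first block of synthetic cultivars, test blends a
    disjoint block (new cultivars, as in an external validation batch). The
    marker variables of the scenario are the blend columns. Returns
    ``(train_blends, test_blends)``.
    """
    from .authenticity import SCENARIO_VARIABLES, BlendSpec, generate_blends

    (main_sp, main_sub), (adu_sp, adu_sub) = scenario_species(scenario)
    columns = SCENARIO_VARIABLES[scenario]
    main_tpl = get_template(main_sp, main_sub)
    adu_tpl = get_template(adu_sp, adu_sub)

    def draw(tpl, seed_offset, n, cultivar_offset):
        return sample_profiles(
            tpl,
            SimConfig(seed=seed + seed_offset, n_cultivars=n, cv=cv),
            columns=columns,
            cultivar_offset=cultivar_offset,
        )

    main_train = draw(main_tpl, 1, n_train_cultivars, 0)
    adu_train = draw(adu_tpl, 2, n_train_cultivars, 0)
    main_test = draw(main_tpl, 3, n_test_cultivars, n_train_cultivars)
    adu_test = draw(adu_tpl, 4, n_test_cultivars, n_train_cultivars)
    spec = BlendSpec(
        main_species=main_sp, adulterant=adu_sp,
        purity_levels=tuple(purity_levels),
        include_pure_main=True,
        include_pure_adulterant=include_pure_adulterant,
    )
    return generate_blends(main_train, adu_train, spec), \
        generate_blends(main_test, adu_test, spec)
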