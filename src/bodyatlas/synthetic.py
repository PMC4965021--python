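"""Synthetic anthropometric cohort generator with planted ground truth.

Emulates the statistical structure the two-stage SOM analysis assumes in a
large adult body-scan cohort:

* ~140 body measures organised into correlated blocks (the planted
  counterparts of the meta-measure clusters) plus unclustered singleton
  measures,
* participants drawn from a gender-linked mixture of body-shape components
  (the planted body types), with components placed at the vertices of a
  regular simplex in latent-factor space,
* gender-specific height and weight marginals matching a 40-79 year old
  middle-European study population (men 176 +/- 7 cm, 86 +/- 14 kg; women
  165 +/- 7 cm, 71 +/- 14 kg),
* every measure scaled by the participant's relative body height so the
  downstream height normalization is non-trivial,
* planted missingness: a background MCAR rate everywhere, a few
  near-empty participants (missing rate > 0.5) and a few badly-captured
  measure columns (missing rate > 0.05), exercising all three
  preprocessing filter stages.

Ground-truth labels (measure -> block, participant -> component) are
returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import MeasureTable

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "toy_filter_fixture"]

#: block sizes mirroring a 13-cluster / 123-measure feature structure
DEFAULT_BLOCK_SIZES = (27, 18, 14, 12, 10, 9, 8, 7, 6, 4, 3, 3, 2)


class ConfigError(ValueError):
    """Raised for inconsistent cohort configurations."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generative model.

    Defaults reproduce the desk-scale study conditions: 13 correlated
    blocks totalling 123 measures plus 17 singletons (140 raw measures, of
    which the 6 "bad" high-missingness columns are singletons, so the
    filtered table keeps 123 block measures + 11 singletons = 134), four
    gender-linked body-shape components, and a 2,000-participant cohort.
    """

    n_participants: int = 2000
    measures_per_block: tuple = DEFAULT_BLOCK_SIZES
    n_singleton_measures: int = 17
    n_body_types: int = 4
    gender_fraction_female: float = 0.514
    #: per-component probability that a member is female; None -> first half
    #: of the components strongly female (0.9), second half strongly male (0.1)
    body_type_gender_affinity: tuple | None = None
    component_separation: float = 5.0
    within_block_correlation: float = 0.8
    noise_sd: float = 1.0
    height_mean_by_gender: dict = field(default_factory=lambda: {"F": 165.0, "M": 176.0})
    height_sd_by_gender: dict = field(default_factory=lambda: {"F": 7.0, "M": 7.0})
    weight_mean_by_gender: dict = field(default_factory=lambda: {"F": 71.0, "M": 86.0})
    weight_sd_by_gender: dict = field(default_factory=lambda: {"F": 14.0, "M": 14.0})
    age_range: tuple = (40.0, 79.0)
    missing_rate_background: float = 0.001
    missing_rate_bad_participants: float = 0.6
    missing_rate_bad_measures: float = 0.10
    n_bad_participants: int = 10
    n_bad_measures: int = 6
    #: blocks whose latent factor drives waist / hip circumference
    waist_block: int = 0
    hip_block: int = 1
    seed: int = 0

    @property
    def n_blocks(self) -> int:
        return len(self.measures_per_block)

    @property
    def n_measures(self) -> int:
        return int(sum(self.measures_per_block)) + self.n_singleton_measures

    def resolved_affinity(self) -> np.ndarray:
        if self.body_type_gender_affinity is not None:
            aff = np.asarray(self.body_type_gender_affinity, dtype=float)
        else:
            aff = np.where(np.arange(self.n_body_types) < self.n_body_types / 2, 0.9, 0.1)
        return aff

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be positive")
        if self.n_blocks < 1 or any(m < 1 for m in self.measures_per_block):
            raise ConfigError("measures_per_block must be positive counts")
        if self.n_singleton_measures < 0:
            raise ConfigError("n_singleton_measures must be >= 0")
        if self.n_body_types < 1:
            raise ConfigError("n_body_types must be positive")
        if self.n_body_types > self.n_blocks:
            raise ConfigError(
                "n_body_types must not exceed n_blocks (components live on a "
                "simplex in latent-factor space)"
            )
        aff = self.resolved_affinity()
        if len(aff) != self.n_body_types or np.any(aff < 0) or np.any(aff > 1):
            raise ConfigError("body_type_gender_affinity must be n_body_types probabilities")
        for p in (
            self.gender_fraction_female,
            self.missing_rate_background,
            self.missing_rate_bad_participants,
            self.missing_rate_bad_measures,
        ):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"proportion out of [0,1]: {p}")
        if not (0.0 < self.within_block_correlation < 1.0):
            raise ConfigError("within_block_correlation must lie in (0,1)")
        if self.component_separation < 0 or self.noise_sd < 0:
            raise ConfigError("component_separation and noise_sd must be >= 0")
        if self.n_bad_participants > self.n_participants:
            raise ConfigError("n_bad_participants exceeds n_participants")
        if self.n_bad_measures > self.n_singleton_measures:
            raise ConfigError(
                "n_bad_measures must not exceed n_singleton_measures (bad "
                "columns are drawn from the singletons)"
            )
        if not (self.n_bad_participants == 0 or self.missing_rate_bad_participants > 0.5):
            raise ConfigError("missing_rate_bad_participants must exceed 0.5")
        if not (self.n_bad_measures == 0 or self.missing_rate_bad_measures > 0.05):
            raise ConfigError("missing_rate_bad_measures must exceed 0.05")
        if not (0 <= self.waist_block < self.n_blocks and 0 <= self.hip_block < self.n_blocks):
            raise ConfigError("waist_block / hip_block out of range")


@dataclass
class SyntheticCohort:
    """Generated cohort: measure matrix, covariates and planted truth."""

    measures: pd.DataFrame          # participants x measures, NaN = planted missing
    covariates: pd.DataFrame        # gender, age, height, weight, waist, hip
    measure_kind: pd.Series         # measure -> kind tag
    truth_block_of_measure: pd.Series   # measure -> "block_00".. or "singleton"
    truth_body_type: pd.Series      # participant -> component index
    latent_factors: pd.DataFrame    # participants x blocks (for diagnostics)
    config: CohortConfig

    def to_measure_table(self) -> MeasureTable:
        return MeasureTable(
            values=self.measures.copy(),
            covariates=self.covariates.copy(),
            measure_kind=self.measure_kind.copy(),
        )


def _simplex_vertices(n_components: int, dim: int, separation: float) -> np.ndarray:
    """Centered vertices of a regular simplex with pairwise distance ``separation``.

    Components occupy the first ``n_components`` latent coordinates; the
    remaining factors carry no component signal.
    """
    v = np.zeros((n_components, dim))
    if n_components > 1:
        v[:, :n_components] = np.eye(n_components) * separation / np.sqrt(2.0)
    v -= v.mean(axis=0, keepdims=True)
    return v


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a cohort from the planted generative model.

    Deterministic given ``config.seed``.  Per participant: gender, then a
    body-shape component conditional on gender (uniform component prior
    tilted by the gender affinity), then one latent factor per block from
    the component's simplex vertex plus unit-variance noise.  Each measure
    is its block factor mixed with independent noise (mixing weight set by
    ``within_block_correlation``), mapped to a measure-specific location
    and scale, and multiplied by the participant's relative body height.
    """
    config.validate()
    cfg = config
    n, B, K = cfg.n_participants, cfg.n_blocks, cfg.n_body_types
    root = np.random.SeedSequence(cfg.seed)
    rng_measures, rng_people, rng_missing = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    # fixed per-measure geometry (locations/scales), independent of n
    block_of = np.repeat(np.arange(B), cfg.measures_per_block)
    block_of = np.concatenate([block_of, np.full(cfg.n_singleton_measures, -1)])
    P = len(block_of)
    loc = rng_measures.uniform(20.0, 150.0, size=P)
    scale = rng_measures.uniform(1.0, 5.0, size=P)

    measure_names, kinds, truth_labels = [], [], []
    block_kind = ["girth" if b % 2 == 0 else "length" for b in range(B)]
    counters = {b: 0 for b in range(-1, B)}
    n_angle = 0
    for b in block_of:
        counters[b] += 1
        if b >= 0:
            measure_names.append(f"block{b:02d}_m{counters[b]:02d}")
            kinds.append(block_kind[b])
            truth_labels.append(f"block_{b:02d}")
        else:
            measure_names.append(f"single_m{counters[b]:02d}")
            # tag two singletons as angles to exercise kind-based exemptions
            kinds.append("angle" if n_angle < 2 else "length")
            n_angle += 1 if n_angle < 2 else 0
            truth_labels.append("singleton")

    # participants: gender -> component -> latent factors
    gender = np.where(rng_people.random(n) < cfg.gender_fraction_female, "F", "M")
    aff = cfg.resolved_affinity()
    p_comp_given_f = aff / aff.sum() if aff.sum() > 0 else np.full(K, 1.0 / K)
    male_aff = 1.0 - aff
    p_comp_given_m = male_aff / male_aff.sum() if male_aff.sum() > 0 else np.full(K, 1.0 / K)
    comp = np.empty(n, dtype=int)
    is_f = gender == "F"
    comp[is_f] = rng_people.choice(K, size=int(is_f.sum()), p=p_comp_given_f)
    comp[~is_f] = rng_people.choice(K, size=int((~is_f).sum()), p=p_comp_given_m)

    vertices = _simplex_vertices(K, B, cfg.component_separation)
    factors = vertices[comp] + rng_people.standard_normal((n, B))

    # covariates
    h_mean = np.where(is_f, cfg.height_mean_by_gender["F"], cfg.height_mean_by_gender["M"])
    h_sd = np.where(is_f, cfg.height_sd_by_gender["F"], cfg.height_sd_by_gender["M"])
    height = h_mean + h_sd * rng_people.standard_normal(n)
    w_mean = np.where(is_f, cfg.weight_mean_by_gender["F"], cfg.weight_mean_by_gender["M"])
    w_sd = np.where(is_f, cfg.weight_sd_by_gender["F"], cfg.weight_sd_by_gender["M"])
    weight = np.clip(w_mean + w_sd * rng_people.standard_normal(n), 30.0, None)
    age = rng_people.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    waist = (
        np.where(is_f, 91.0, 101.0)
        + 6.0 * factors[:, cfg.waist_block]
        + 2.0 * rng_people.standard_normal(n)
    )
    hip = (
        np.where(is_f, 108.0, 105.0)
        + 5.0 * factors[:, cfg.hip_block]
        + 2.0 * rng_people.standard_normal(n)
    )
    waist = np.clip(waist, 40.0, None)
    hip = np.clip(hip, 50.0, None)

    # measures: factor + noise, measure-specific affine map, height scaling
    w_blk = cfg.within_block_correlation
    eps = rng_people.standard_normal((n, P)) * cfg.noise_sd
    raw = np.empty((n, P))
    in_block = block_of >= 0
    raw[:, in_block] = (
        np.sqrt(w_blk) * factors[:, block_of[in_block]]
        + np.sqrt(1.0 - w_blk) * eps[:, in_block]
    )
    raw[:, ~in_block] = eps[:, ~in_block]

    mean_height = (
        cfg.gender_fraction_female * cfg.height_mean_by_gender["F"]
        + (1.0 - cfg.gender_fraction_female) * cfg.height_mean_by_gender["M"]
    )
    values = (loc[None, :] + scale[None, :] * raw) * (height / mean_height)[:, None]

    # planted missingness
    mask = rng_missing.random((n, P)) < cfg.missing_rate_background
    bad_rows = rng_missing.choice(n, size=cfg.n_bad_participants, replace=False)
    mask[bad_rows] |= (
        rng_missing.random((cfg.n_bad_participants, P)) < cfg.missing_rate_bad_participants
    )
    singles = np.flatnonzero(~in_block)
    bad_cols = rng_missing.choice(singles, size=cfg.n_bad_measures, replace=False)
    mask[:, bad_cols] |= (
        rng_missing.random((n, cfg.n_bad_measures)).T < cfg.missing_rate_bad_measures
    ).T
    values = np.where(mask, np.nan, values)

    pid = pd.Index([f"p{i:05d}" for i in range(n)], name="participant")
    measures = pd.DataFrame(values, index=pid, columns=measure_names)
    covariates = pd.DataFrame(
        {
            "gender": gender,
            "age": age,
            "height": height,
            "weight": weight,
            "waist": waist,
            "hip": hip,
        },
        index=pid,
    )
    return SyntheticCohort(
        measures=measures,
        covariates=covariates,
        measure_kind=pd.Series(kinds, index=measure_names),
        truth_block_of_measure=pd.Series(truth_labels, index=measure_names),
        truth_body_type=pd.Series(comp, index=pid),
        latent_factors=pd.DataFrame(
            factors, index=pid, columns=[f"factor_{b:02d}" for b in range(B)]
        ),
        config=cfg,
    )


def toy_filter_fixture() -> MeasureTable:
    """Hand-built 22 x 6 table exercising all three filter stages.

    Missingness pattern (``x`` = missing), rows p00..p21, columns m0..m5::

        p00 : m0, m1, m2, m4 missing  (4/6 = 67% > 50%)   -> stage 1 removes p00
        p01 : m5 missing
        p02 : m5 missing               m5 missing in 2/21 = 9.5% > 5%
                                                           -> stage 2 removes m5
        p03 : m4 missing               m4 missing in 1/21 = 4.8% <= 5%, kept
                                                           -> stage 3 removes p03
        p04..p21 : complete

    Survivors: participants {p01, p02, p04..p21} x measures {m0..m4}.
    The stage order matters: applied measures-first on all 22 rows, m4 is
    missing in 2/22 = 9.1% > 5% and would be removed instead of p03.
    """
    n, cols = 22, ["m0", "m1", "m2", "m3", "m4", "m5"]
    pid = pd.Index([f"p{i:02d}" for i in range(n)], name="participant")
    rng = np.random.default_rng(12345)
    values = pd.DataFrame(
        np.round(rng.uniform(50.0, 120.0, size=(n, len(cols))), 1),
        index=pid, columns=cols,
    )
    values.loc["p00", ["m0", "m1", "m2", "m4"]] = np.nan
    values.loc["p01", "m5"] = np.nan
    values.loc["p02", "m5"] = np.nan
    values.loc["p03", "m4"] = np.nan
    covariates = pd.DataFrame(
        {
            "gender": np.where(np.arange(n) % 2 == 0, "F", "M"),
            "age": np.round(rng.uniform(40, 79, size=n), 1),
            "height": np.round(rng.normal(170, 7, size=n), 1),
        },
        index=pid,
    )
    return MeasureTable(values=values, covariates=covariates)


#: hand-derived survivor sets of :func:`toy_filter_fixture` under the
#: default thresholds (participant 0.5, measure 0.05)
TOY_FIXTURE_EXPECTED = {
    "stage1_removed": ("p00",),
    "stage2_removed": ("m5",),
    "stage3_removed": ("p03",),
    "surviving_measures": ("m0", "m1", "m2", "m3", "m4"),
    "surviving_participants": tuple(
        f"p{i:02d}" for i in range(22) if i not in (0, 3)
    ),
}
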