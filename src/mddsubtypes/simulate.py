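"""Synthetic cohorts with planted subtype structure.

Real participant-level data behind this kind of symptom-subtyping study are
rarely shareable, so every downstream stage is exercised on synthetic cohorts
that emulate the statistical structure the analysis assumes:

* three planted subtypes — a moderate/typical profile, a severe/typical
  profile with insomnia and decreased appetite, and a severe profile with
  increased appetite and weight gain;
* mutually exclusive opposite-polarity item pairs (a subject cannot report
  both weight loss and weight gain);
* negative inter-item correlations between the members of those pairs of
  roughly the magnitudes seen in questionnaire data (appetite about -0.49,
  weight about -0.31; see :func:`study_cohort_spec` for why the default
  cohort sets no sleep target);
* ROI tables with additive covariate effects (age, sex, intracranial volume)
  and an optional planted group deficit (lower anterior insula surface area
  in the increased-appetite subtype).

Ordinal scores come from a latent Gaussian per item (mean = 3 x propensity
plus the profile's severity shift for non-neurovegetative items, sd =
``noise_sd``) rounded and clipped to {0,..,3}.  Opposite-polarity exclusivity
is enforced by a shared per-pair "direction" latent: the profile's polarity
(or a fair coin when the profile endorses neither side) picks which side may
be nonzero.  A negative correlation target for a pair is met in closed form
(no tuning loop): the target rho fixes the endorsement probabilities of the
two named items via rho^2 = p_a p_b / ((1-p_a)(1-p_b)), and the generator
thins (zeroes) or flips (moves across sides) just enough subjects to move the
natural marginals onto (p_a, p_b).  With a target present the pair scores are
therefore stochastic even at ``noise_sd = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .items import (
    MAX_SCORE,
    NEUROVEGETATIVE_ITEMS,
    POLARITY_PAIRS,
    QIDS_ITEMS,
    ROI_KINDS,
    ROI_NAMES,
    item_index,
    polarity_pair_of,
)
from .prep import SymptomMatrix, ValidationError

_NON_NEUROVEG_IDX = np.array(
    [i for i, it in enumerate(QIDS_ITEMS) if it not in NEUROVEGETATIVE_ITEMS]
)


@dataclass
class SubtypeProfileSpec:
    """One planted subtype: per-item propensities, severity shift, prevalence.

    ``item_propensities`` scale the expected item score (latent mean is
    3 x propensity); ``severity_shift`` is added to the latent mean of every
    non-neurovegetative item, raising overall severity without touching the
    sleep/appetite signature.
    """

    name: str
    item_propensities: tuple[float, ...]
    severity_shift: float = 0.0
    prevalence: float = 1.0

    def __post_init__(self) -> None:
        props = tuple(float(v) for v in self.item_propensities)
        if len(props) != len(QIDS_ITEMS):
            raise ValidationError(
                f"profile {self.name!r}: expected {len(QIDS_ITEMS)} "
                f"propensities, got {len(props)}"
            )
        for item, v in zip(QIDS_ITEMS, props):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"profile {self.name!r}: propensity for item {item!r} "
                    f"is {v}, outside [0, 1]"
                )
        for side_a, side_b in POLARITY_PAIRS:
            a = any(props[item_index(i)] > 0 for i in side_a)
            b = any(props[item_index(i)] > 0 for i in side_b)
            if a and b:
                raise ValidationError(
                    f"profile {self.name!r}: both sides of the polarity pair "
                    f"{side_a} / {side_b} have positive propensity"
                )
        self.item_propensities = props

    def polarity(self, pair_idx: int) -> str | None:
        """'a', 'b' or None: which side of a pair this profile endorses."""
        side_a, side_b = POLARITY_PAIRS[pair_idx]
        if any(self.item_propensities[item_index(i)] > 0 for i in side_a):
            return "a"
        if any(self.item_propensities[item_index(i)] > 0 for i in side_b):
            return "b"
        return None

    def latent_means(self) -> np.ndarray:
        mu = 3.0 * np.asarray(self.item_propensities)
        mu[_NON_NEUROVEG_IDX] += self.severity_shift
        return mu

    def expected_scores(self) -> np.ndarray:
        """Zero-noise item vector: rounded, clipped latent means."""
        return np.clip(np.rint(self.latent_means()), 0, MAX_SCORE).astype(int)


@dataclass
class CohortSpec:
    """A symptom cohort: profiles, prevalences, noise, correlation targets."""

    n_subjects: int
    profiles: list[SubtypeProfileSpec]
    noise_sd: float = 0.0
    inter_item_correlation_targets: dict[tuple[str, str], float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < len(self.profiles):
            raise ValidationError("n_subjects must be >= number of profiles")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        total = sum(p.prevalence for p in self.profiles)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"prevalences sum to {total}, not 1")
        if self.inter_item_correlation_targets:
            seen = set()
            for (a, b), rho in self.inter_item_correlation_targets.items():
                pa, pb = polarity_pair_of(a), polarity_pair_of(b)
                if pa is None or pa != pb:
                    raise ValidationError(
                        f"target items ({a!r}, {b!r}) are not an "
                        "opposite-polarity pair"
                    )
                side_a, _ = POLARITY_PAIRS[pa]
                if (a in side_a) == (b in side_a):
                    raise ValidationError(
                        f"target items ({a!r}, {b!r}) lie on the same side"
                    )
                if not -1.0 < rho <= 0.0:
                    raise ValidationError(
                        f"correlation target for ({a!r}, {b!r}) must lie in "
                        f"(-1, 0], got {rho}"
                    )
                if pa in seen:
                    raise ValidationError(
                        f"multiple targets for polarity pair {pa}"
                    )
                seen.add(pa)


@dataclass
class RoiEffectSpec:
    """An additive group shift on one ROI measure, with optional overrides."""

    roi_name: str
    group: str
    effect: float
    covariate_slopes: dict[str, float] | None = None
    residual_sd: float | None = None

    def __post_init__(self) -> None:
        if self.roi_name not in ROI_NAMES:
            raise ValidationError(f"unknown ROI measure: {self.roi_name!r}")
        if self.residual_sd is not None and self.residual_sd <= 0:
            raise ValidationError("residual_sd must be positive")
        if (
            ROI_KINDS[self.roi_name] == "thickness"
            and self.covariate_slopes
            and self.covariate_slopes.get("icv", 0.0) != 0.0
        ):
            raise ValidationError(
                "thickness measures must have zero ICV slope"
            )


# ---------------------------------------------------------------------------
# symptom cohort generation


def _endorse_prob(latent_mean: float, sd: float) -> float:
    """P(rounded latent score >= 1)."""
    if sd == 0.0:
        return 1.0 if latent_mean >= 0.5 else 0.0
    return float(norm.sf((0.5 - latent_mean) / sd))


def _pair_plan(spec: CohortSpec, pair_idx: int, item_a: str, item_b: str,
               rho: float) -> dict:
    """Closed-form thinning / flipping plan meeting a correlation target.

    Natural marginals q of the two named items follow from the profiles,
    prevalences and noise; the target |rho| implies endorsement probabilities
    (p_a, p_b) with rho^2 = p_a p_b / ((1-p_a)(1-p_b)).  When a common scale
    s <= 1 exists with (p_a, p_b) = (s q_a, s q_b), both sides are thinned by
    s; otherwise the larger side is kept and the smaller side's marginal is
    raised to the implied value by flipping subjects across.
    """
    r2 = rho * rho

    def natural(item: str, side: str) -> float:
        idx = item_index(item)
        q = 0.0
        for prof in spec.profiles:
            pol = prof.polarity(pair_idx)
            gate = 1.0 if pol == side else (0.5 if pol is None else 0.0)
            if gate:
                q += prof.prevalence * gate * _endorse_prob(
                    prof.latent_means()[idx], spec.noise_sd
                )
        return q

    q_a, q_b = natural(item_a, "a"), natural(item_b, "b")
    plan = {"keep_a": 1.0, "keep_b": 1.0, "flip_to": None, "flip_prob": 0.0}
    if rho == 0.0:
        return plan
    # the minority side usually carries the subtype-defining symptoms
    # (e.g. increased appetite), so it is left intact whenever the target
    # can be met by thinning the majority side alone
    if q_a >= q_b:
        maj_q, min_q = q_a, q_b
        keep_maj, keep_min, flip_to = "keep_a", "keep_b", "b"
    else:
        maj_q, min_q = q_b, q_a
        keep_maj, keep_min, flip_to = "keep_b", "keep_a", "a"
    if maj_q <= 0:
        raise ValidationError(
            f"correlation target for ({item_a!r}, {item_b!r}) is "
            "unachievable: neither side is endorsed under these profiles"
        )
    if min_q > 0:
        t = r2 * (1.0 - min_q) / min_q
        p_maj = t / (1.0 + t)
        if p_maj <= maj_q:
            plan[keep_maj] = p_maj / maj_q
            return plan
    # natural correlation too weak even with the full majority side:
    # raise (or create) the minority marginal instead
    t = r2 * (1.0 - maj_q) / maj_q
    p_min = t / (1.0 + t)
    if p_min <= min_q and min_q > 0:
        plan[keep_min] = p_min / min_q
    else:
        plan["flip_to"] = flip_to
        plan["flip_prob"] = min(1.0, (p_min - min_q) / maj_q)
    return plan


def generate_symptom_cohort(spec: CohortSpec
                            ) -> tuple[SymptomMatrix, np.ndarray]:
    """Draw a cohort from a :class:`CohortSpec`.

    Returns the symptom matrix and the true subtype label per subject.
    Reproducible given ``spec.seed``; opposite-polarity exclusivity holds for
    every generated subject.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    prev = np.array([p.prevalence for p in spec.profiles])
    assign = rng.choice(len(spec.profiles), size=n, p=prev)
    mu = np.vstack([p.latent_means() for p in spec.profiles])[assign]
    if spec.noise_sd > 0:
        latent = mu + rng.normal(0.0, spec.noise_sd, size=mu.shape)
    else:
        latent = mu.copy()
    scores = np.clip(np.rint(latent), 0, MAX_SCORE).astype(np.int64)

    targets: dict[int, tuple[str, str, float]] = {}
    if spec.inter_item_correlation_targets:
        for (a, b), rho in spec.inter_item_correlation_targets.items():
            pair_idx = polarity_pair_of(a)
            side_a, _ = POLARITY_PAIRS[pair_idx]
            if a in side_a:
                targets[pair_idx] = (a, b, rho)
            else:
                targets[pair_idx] = (b, a, rho)

    polarity = np.array(
        [[{"a": 0, "b": 1, None: -1}[p.polarity(i)]
          for i in range(len(POLARITY_PAIRS))]
         for p in spec.profiles]
    )[assign]                                    # n x n_pairs; -1 = none

    for pair_idx, (side_a, side_b) in enumerate(POLARITY_PAIRS):
        ia = np.array([item_index(i) for i in side_a])
        ib = np.array([item_index(i) for i in side_b])
        side = polarity[:, pair_idx].astype(float)
        none_mask = side < 0
        if none_mask.any():
            side[none_mask] = (rng.random(none_mask.sum()) < 0.5).astype(float)
        if pair_idx in targets:
            item_a, item_b, rho = targets[pair_idx]
            plan = _pair_plan(spec, pair_idx, item_a, item_b, rho)
            if plan["flip_prob"] > 0:
                flip_from = 0.0 if plan["flip_to"] == "b" else 1.0
                cand = side == flip_from
                flips = cand & (rng.random(n) < plan["flip_prob"])
                side[flips] = 1.0 - flip_from
                # flipped subjects endorse only the named minority item at a
                # typical endorsed level
                named = item_index(item_b if plan["flip_to"] == "b" else item_a)
                own = ib if plan["flip_to"] == "b" else ia
                lat = 2.0 + (rng.normal(0.0, spec.noise_sd, flips.sum())
                             if spec.noise_sd > 0 else 0.0)
                scores[np.ix_(flips, own)] = 0
                scores[flips, named] = np.clip(np.rint(lat), 1, MAX_SCORE
                                               ).astype(np.int64)
            for keep_key, mask_side in (("keep_a", 0.0), ("keep_b", 1.0)):
                keep = plan[keep_key]
                if keep < 1.0:
                    on_side = side == mask_side
                    dropped = on_side & (rng.random(n) >= keep)
                    cols = ia if mask_side == 0.0 else ib
                    scores[np.ix_(dropped, cols)] = 0
        # zero the disallowed side
        scores[np.ix_(side == 0.0, ib)] = 0
        scores[np.ix_(side == 1.0, ia)] = 0

    labels = np.array([spec.profiles[g].name for g in assign])
    ids = [f"S{i:04d}" for i in range(n)]
    return SymptomMatrix(ids, scores), labels


def check_polarity_exclusivity(matrix: SymptomMatrix) -> bool:
    """True iff no subject endorses both sides of any polarity pair."""
    for side_a, side_b in POLARITY_PAIRS:
        ia = [matrix.item_names.index(i) for i in side_a
              if i in matrix.item_names]
        ib = [matrix.item_names.index(i) for i in side_b
              if i in matrix.item_names]
        a = matrix.scores[:, ia].sum(axis=1) > 0
        b = matrix.scores[:, ib].sum(axis=1) > 0
        if (a & b).any():
            return False
    return True


def generate_null_cohort(n_subjects: int, marginal_item_distributions=None,
                         seed: int = 0) -> SymptomMatrix:
    """Structure-free cohort: items sampled independently from marginals.

    ``marginal_item_distributions`` is a (16, 4) array of probabilities over
    scores 0-3 (rows per item), a single length-4 vector applied to every
    item, or None for uniform marginals.  No cluster structure exists by
    construction, so this is the reference input for type-I-error checks of
    the permutation machinery.
    """
    if marginal_item_distributions is None:
        marg = np.full((len(QIDS_ITEMS), 4), 0.25)
    else:
        marg = np.asarray(marginal_item_distributions, dtype=float)
        if marg.ndim == 1:
            marg = np.tile(marg, (len(QIDS_ITEMS), 1))
    if marg.shape != (len(QIDS_ITEMS), 4):
        raise ValidationError(f"marginals must be ({len(QIDS_ITEMS)}, 4)")
    if (marg < 0).any() or np.any(np.abs(marg.sum(axis=1) - 1.0) > 1e-9):
        raise ValidationError("each marginal must be a probability vector")
    rng = np.random.default_rng(seed)
    scores = np.column_stack([
        rng.choice(4, size=n_subjects, p=row) for row in marg
    ])
    ids = [f"N{i:04d}" for i in range(n_subjects)]
    return SymptomMatrix(ids, scores)


# ---------------------------------------------------------------------------
# ROI cohort generation

#: synthetic per-measure baselines: plausible young-adult bilateral means
#: (area mm^2, thickness mm, volume mm^3)
ROI_BASELINES: dict[str, float] = {
    "rostral_acc_area": 780.0,
    "rostral_acc_thickness": 2.90,
    "caudal_acc_area": 730.0,
    "caudal_acc_thickness": 2.90,
    "medial_ofc_area": 1900.0,
    "medial_ofc_thickness": 2.45,
    "anterior_insula_area": 420.0,
    "anterior_insula_thickness": 3.60,
    "posterior_insula_area": 310.0,
    "posterior_insula_thickness": 3.50,
    "hippocampus_volume": 4500.0,
    "amygdala_volume": 1760.0,
    "ventral_striatum_volume": 630.0,
}

DEFAULT_COVARIATE_RANGES: dict[str, float | tuple[float, float]] = {
    "age": (15.0, 25.0),     # uniform years
    "sex_p": 0.5,            # balanced binary, coded 0/1
    "icv_mean": 1.5e6,       # mm^3
    "icv_sd": 1.5e5,
}


def _default_slopes(roi: str) -> dict[str, float]:
    base = ROI_BASELINES[roi]
    if ROI_KINDS[roi] == "thickness":
        return {"age": -0.01, "sex": 0.0, "icv": 0.0}
    return {"age": 0.0, "sex": 0.04 * base, "icv": 0.25 * base / 1.5e6}


def _default_residual_sd(roi: str) -> float:
    base = ROI_BASELINES[roi]
    if ROI_KINDS[roi] == "thickness":
        return 0.12
    return 0.09 * base


def sia_insula_effect(effect: float = -40.0) -> list[RoiEffectSpec]:
    """The planted deficit: lower anterior insula surface area in the
    increased-appetite (SIA) subtype."""
    return [RoiEffectSpec("anterior_insula_area", "SIA", effect)]


def generate_roi_cohort(labels, effect_specs: list[RoiEffectSpec] | None = None,
                        covariate_ranges: dict | None = None,
                        seed: int = 0,
                        residual_sd_scale: float = 1.0) -> pd.DataFrame:
    """ROI table for the given group labels.

    Each measure is baseline + covariate terms + group effect + Gaussian
    noise.  Covariates: age ~ Uniform(range), sex ~ Bernoulli(0.5) coded 0/1,
    ICV ~ Normal(mean, sd); age and ICV enter centered so the baselines are
    the expected values of an average subject.  ``residual_sd_scale`` scales
    every residual sd (0 gives noise-free tables for exact checks).
    """
    labels = np.asarray([str(v) for v in labels])
    if labels.size == 0:
        raise ValidationError("labels must be nonempty")
    groups = set(labels)
    effect_specs = effect_specs or []
    for es in effect_specs:
        if es.group not in groups:
            raise ValidationError(
                f"effect group {es.group!r} not among labels {sorted(groups)}"
            )
    ranges = dict(DEFAULT_COVARIATE_RANGES)
    if covariate_ranges:
        ranges.update(covariate_ranges)
    rng = np.random.default_rng(seed)
    n = labels.size
    age = rng.uniform(*ranges["age"], size=n)
    sex = (rng.random(n) < ranges["sex_p"]).astype(int)
    icv = rng.normal(ranges["icv_mean"], ranges["icv_sd"], size=n)
    age_mid = 0.5 * (ranges["age"][0] + ranges["age"][1])

    out = pd.DataFrame({
        "subject_id": [f"R{i:04d}" for i in range(n)],
        "group": labels,
        "age": age,
        "sex": sex,
        "icv": icv,
    })
    by_roi: dict[str, list[RoiEffectSpec]] = {}
    for es in effect_specs:
        by_roi.setdefault(es.roi_name, []).append(es)
    for roi in ROI_NAMES:
        slopes = _default_slopes(roi)
        sd = _default_residual_sd(roi)
        shift = np.zeros(n)
        for es in by_roi.get(roi, []):
            if es.covariate_slopes is not None:
                slopes = {**{"age": 0.0, "sex": 0.0, "icv": 0.0},
                          **es.covariate_slopes}
            if es.residual_sd is not None:
                sd = es.residual_sd
            shift = shift + np.where(labels == es.group, es.effect, 0.0)
        values = (
            ROI_BASELINES[roi]
            + slopes["age"] * (age - age_mid)
            + slopes["sex"] * sex
            + slopes["icv"] * (icv - ranges["icv_mean"])
            + shift
        )
        sd_eff = sd * residual_sd_scale
        if sd_eff > 0:
            values = values + rng.normal(0.0, sd_eff, size=n)
        out[roi] = values
    return out


# ---------------------------------------------------------------------------
# study-shaped default cohorts

_P = {name: i for i, name in enumerate(QIDS_ITEMS)}


def _props(**kwargs: float) -> tuple[float, ...]:
    v = [0.0] * len(QIDS_ITEMS)
    for name, val in kwargs.items():
        v[_P[name]] = val
    return tuple(v)


def study_profiles() -> list[SubtypeProfileSpec]:
    """Three planted subtypes mirroring the moderate / severe-typical /
    severe-increased-appetite structure, with study-like prevalences
    (111 : 105 : 59)."""
    mod = SubtypeProfileSpec(
        name="MOD",
        item_propensities=_props(
            sleep_onset_insomnia=0.40, mid_nocturnal_insomnia=0.45,
            early_morning_awakening=0.30, sad_mood=0.55,
            decreased_appetite=0.40, weight_loss=0.30,
            concentration=0.55, self_view=0.45, suicidal_ideation=0.25,
            general_interest=0.55, fatigue=0.60,
            psychomotor_slowing=0.25, psychomotor_agitation=0.30,
        ),
        severity_shift=0.0,
        prevalence=111 / 275,
    )
    sda = SubtypeProfileSpec(
        name="SDA",
        item_propensities=_props(
            sleep_onset_insomnia=0.75, mid_nocturnal_insomnia=0.80,
            early_morning_awakening=0.70, sad_mood=0.65,
            decreased_appetite=0.75, weight_loss=0.55,
            concentration=0.60, self_view=0.65, suicidal_ideation=0.40,
            general_interest=0.60, fatigue=0.65,
            psychomotor_slowing=0.40, psychomotor_agitation=0.40,
        ),
        severity_shift=0.8,
        prevalence=105 / 275,
    )
    sia = SubtypeProfileSpec(
        name="SIA",
        item_propensities=_props(
            sleep_onset_insomnia=0.45, mid_nocturnal_insomnia=0.55,
            early_morning_awakening=0.35, sad_mood=0.65,
            increased_appetite=0.70, weight_gain=0.60,
            concentration=0.60, self_view=0.65, suicidal_ideation=0.40,
            general_interest=0.60, fatigue=0.65,
            psychomotor_slowing=0.35, psychomotor_agitation=0.40,
        ),
        severity_shift=0.8,
        prevalence=59 / 275,
    )
    return [mod, sda, sia]


def study_cohort_spec(n_subjects: int = 275, noise_sd: float = 0.6,
                      seed: int = 0) -> CohortSpec:
    """The default study-shaped cohort: three subtypes, latent noise, and
    opposite-polarity correlation targets for the appetite and weight pairs.

    No sleep target is set: under hard insomnia/hypersomnia exclusivity and
    insomnia-dominant profiles, any negative sleep correlation implies a
    hypersomnia endorsement rate below 1%, and standardizing such a
    near-constant column turns its few endorsers into extreme outliers that
    do not exist in real questionnaire data.  Sleep exclusivity itself is
    still enforced for every subject.
    """
    return CohortSpec(
        n_subjects=n_subjects,
        profiles=study_profiles(),
        noise_sd=noise_sd,
        inter_item_correlation_targets={
            ("decreased_appetite", "increased_appetite"): -0.49,
            ("weight_loss", "weight_gain"): -0.31,
        },
        seed=seed,
    )


def noiseless_cohort_spec(n_subjects: int = 90, seed: int = 0) -> CohortSpec:
    """Zero-noise planted cohort (no correlation targets): every subject's
    item vector is exactly its profile's rounded expectation."""
    return CohortSpec(
        n_subjects=n_subjects,
        profiles=study_profiles(),
        noise_sd=0.0,
        inter_item_correlation_targets=None,
        seed=seed,
    )


def cohort_spec_from_config(doc: dict) -> CohortSpec:
    """Build a CohortSpec from a nested config mapping (e.g. parsed YAML)."""
    profiles = []
    for p in doc["profiles"]:
        props = p["item_propensities"]
        if isinstance(props, dict):
            props = _props(**props)
        profiles.append(SubtypeProfileSpec(
            name=p["name"],
            item_propensities=tuple(props),
            severity_shift=float(p.get("severity_shift", 0.0)),
            prevalence=float(p["prevalence"]),
        ))
    targets = None
    if doc.get("inter_item_correlation_targets"):
        targets = {
            tuple(k.split("/")) if isinstance(k, str) else tuple(k): float(v)
            for k, v in doc["inter_item_correlation_targets"].items()
        }
    return CohortSpec(
        n_subjects=int(doc["n_subjects"]),
        profiles=profiles,
        noise_sd=float(doc.get("noise_sd", 0.0)),
        inter_item_correlation_targets=targets,
        seed=int(doc.get("seed", 0)),
    )
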