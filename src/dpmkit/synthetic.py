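"""Calibrated stochastic generator of synthetic DPM cohorts.

The observational data behind the published cohort statistics were
never deposited, so every cohort-level operation in this toolkit is
exercised against synthetic cohorts whose *marginal* statistics are
calibrated to those published values: count distributions for options
and cues (overall and in the generation phase), the structural
probabilities of the three-phase pattern, confidence endpoint
distributions split by outcome, and contextual covariates with target
correlations.

Calibration strategy
--------------------
* Counts and confidence endpoints are *discretized truncated normals*:
  integer k in [lo, hi] gets the normal mass of (k-1/2, k+1/2] with the
  boundary cells absorbing the tails.  The location parameter is solved
  numerically so the post-truncation mean equals the configured mean
  exactly; the configured SD is used as the shape parameter (the
  realized SD is therefore close to, not exactly, the configured one).
* Point masses at the scale extremes (final diagnoses rated +4,
  excluded options rated -4) are imposed first; the remaining mass is a
  discretized truncated normal over the rest of the support whose mean
  is chosen so the mixture mean equals the configured mean exactly.
* Structural probabilities interact (a case whose options all appear in
  phase 1 cannot have a phase-2 addition; the final diagnosis of such a
  case is necessarily a phase-1 option).  Conditional probabilities are
  derived from the configured marginals so the *overall* rates come out
  exactly as configured.
* Covariate correlations are induced by rank matching (Iman-Conover
  style reordering of independently drawn marginal values against the
  anchor variable), so the marginal distributions stay exactly as
  calibrated while the correlation converges to its target.

Reproducibility: one root seed per cohort; each case uses a substream
keyed by its index, so cohorts are reproducible and order-independent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from math import sqrt
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize as _opt
from scipy import stats as _sps

from . import concordance as _concordance
from .core import (
    CaseMetadata,
    ConfidenceLevel,
    Cue,
    CueSource,
    DecisionProcessMatrix,
    DpmError,
    OptionTrack,
    Outcome,
    TriState,
    Unit,
    UnitKind,
)

__all__ = [
    "CountSpec",
    "GeneratorConfig",
    "ConfigError",
    "discretized_pmf",
    "sample_count",
    "generate_case",
    "generate_cohort",
    "generate_rater_pairs",
]


class ConfigError(DpmError, ValueError):
    """An infeasible generator configuration."""


@dataclass(frozen=True)
class CountSpec:
    """An integer-valued distribution given by mean, SD and hard bounds."""

    mean: float
    sd: float
    lo: int
    hi: int

    def validate(self, name: str = "count spec") -> None:
        if self.lo > self.hi:
            raise ConfigError(f"{name}: bounds out of order ({self.lo} > {self.hi})")
        if self.lo == self.hi:
            return  # degenerate: constant, mean irrelevant
        if self.sd < 0:
            raise ConfigError(f"{name}: negative SD")
        if self.sd == 0:
            if abs(self.mean - round(self.mean)) > 1e-9 or not self.lo <= round(self.mean) <= self.hi:
                raise ConfigError(f"{name}: SD 0 requires an integer mean within bounds")
            return
        if not self.lo < self.mean < self.hi:
            raise ConfigError(f"{name}: mean {self.mean} not strictly inside [{self.lo}, {self.hi}]")


# ---------------------------------------------------------------------------
# Discretized truncated normal with exact mean calibration
# ---------------------------------------------------------------------------


def _raw_pmf(mu: float, sigma: float, lo: int, hi: int) -> np.ndarray:
    ks = np.arange(lo, hi + 1, dtype=float)
    upper = np.where(ks == hi, np.inf, ks + 0.5)
    lower = np.where(ks == lo, -np.inf, ks - 0.5)
    p = _sps.norm.cdf((upper - mu) / sigma) - _sps.norm.cdf((lower - mu) / sigma)
    s = p.sum()
    if s <= 0:
        raise ConfigError("degenerate discretization")
    return p / s


@lru_cache(maxsize=256)
def _calibrated_pmf(mean: float, sd: float, lo: int, hi: int) -> tuple:
    """PMF over lo..hi whose expectation equals *mean* exactly.

    The location of the underlying normal is solved by root finding;
    the discretized mean is strictly increasing in the location, so the
    root is unique.
    """
    ks = np.arange(lo, hi + 1, dtype=float)
    if lo == hi:
        return (1.0,)
    if sd == 0:
        p = np.zeros_like(ks)
        p[int(round(mean)) - lo] = 1.0
        return tuple(p)

    def gap(mu: float) -> float:
        return float(_raw_pmf(mu, sd, lo, hi) @ ks) - mean

    span = 10 * sd + (hi - lo)
    mu = _opt.brentq(gap, lo - span, hi + span, xtol=1e-12)
    return tuple(_raw_pmf(mu, sd, lo, hi))


def discretized_pmf(spec: CountSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the calibrated distribution."""
    spec.validate()
    ks = np.arange(spec.lo, spec.hi + 1)
    return ks, np.asarray(_calibrated_pmf(spec.mean, spec.sd, spec.lo, spec.hi))


def sample_count(spec: CountSpec, rng: np.random.Generator, size=None):
    """Draw integer(s) from the calibrated distribution."""
    ks, p = discretized_pmf(spec)
    out = rng.choice(ks, size=size, p=p)
    return int(out) if size is None else out


def _sample_restricted(spec: CountSpec, rng: np.random.Generator, lo: int, hi: int) -> int:
    """Draw from the calibrated pmf renormalized to the window [lo, hi]."""
    ks, p = discretized_pmf(spec)
    mask = (ks >= lo) & (ks <= hi)
    if not mask.any() or p[mask].sum() <= 0:
        raise ConfigError(f"restriction [{lo}, {hi}] leaves no mass for {spec}")
    p = p[mask] / p[mask].sum()
    return int(rng.choice(ks[mask], p=p))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_COUNT_FIELDS = (
    "options",
    "cues",
    "phase1_options",
    "phase1_cues",
    "initial_confidence",
    "final_confidence",
    "excluded_confidence",
    "experience_months",
    "similarity",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All distributional parameters of the synthetic cohort generator.

    Defaults are the published cohort statistics; SDs for covariates the
    source reports only as ranges (experience in months, similarity)
    are set to plausible values covering those ranges.
    """

    n_cases: int = 55
    seed: int = 0
    # count marginals: mean, SD, bounds
    options: CountSpec = CountSpec(3.2, 1.8, 1, 9)
    cues: CountSpec = CountSpec(7.9, 2.9, 3, 17)
    phase1_options: CountSpec = CountSpec(2.3, 1.4, 1, 6)
    phase1_cues: CountSpec = CountSpec(1.9, 0.8, 1, 4)
    # structural probabilities
    p_final_in_phase1: float = 0.87
    p_phase2_addition: float = 0.45
    p_final_rated_max: float = 0.67
    p_excluded_rated_min: float = 0.54
    p_time_pressure: float = 0.20
    p_stress: float = 0.15
    p_case_experience: float = 46 / 55
    # confidence endpoint marginals
    initial_confidence: CountSpec = CountSpec(1.76, 0.81, -2, 3)
    final_confidence: CountSpec = CountSpec(3.56, 0.71, 1, 4)
    excluded_confidence: CountSpec = CountSpec(-2.50, 2.08, -4, 2)
    # contextual covariates
    experience_months: CountSpec = CountSpec(41.0, 11.0, 23, 69)
    similarity: CountSpec = CountSpec(3.5, 1.5, 1, 6)
    r_experience_phase2_cues: float = -0.35
    rs_similarity_final_confidence: float = 0.31
    # which denominator the provenance report quotes for phase-2 additions
    additions_mean_over: str = "cases_with_additions"  # or "all_cases"
    # phase-2 ratings per option are uniform on 1..max_phase2_ratings
    max_phase2_ratings: int = 4

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for name in _COUNT_FIELDS:
            getattr(self, name).validate(name)
        for name in (
            "p_final_in_phase1",
            "p_phase2_addition",
            "p_final_rated_max",
            "p_excluded_rated_min",
            "p_time_pressure",
            "p_stress",
            "p_case_experience",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} = {p} outside [0, 1]")
        if self.p_final_in_phase1 < 1.0 - self.p_phase2_addition - 1e-12:
            raise ConfigError(
                "p_final_in_phase1 must be >= 1 - p_phase2_addition: cases without "
                "phase-2 additions necessarily pick their final diagnosis in phase 1"
            )
        if self.additions_mean_over not in {"cases_with_additions", "all_cases"}:
            raise ConfigError(f"additions_mean_over: unknown value {self.additions_mean_over!r}")
        if self.max_phase2_ratings < 1:
            raise ConfigError("max_phase2_ratings must be >= 1")
        # feasibility of the endpoint mixtures
        self._rest_spec(self.final_confidence, self.p_final_rated_max, top=True)
        self._rest_spec(self.excluded_confidence, self.p_excluded_rated_min, top=False)
        self._derived_probs()

    @staticmethod
    def _rest_spec(spec: CountSpec, p_extreme: float, top: bool) -> Optional[CountSpec]:
        """Distribution of the non-extreme endpoint mass."""
        if p_extreme >= 1.0:
            return None
        extreme = spec.hi if top else spec.lo
        lo, hi = (spec.lo, spec.hi - 1) if top else (spec.lo + 1, spec.hi)
        m_rest = (spec.mean - p_extreme * extreme) / (1.0 - p_extreme)
        rest = CountSpec(m_rest, spec.sd, lo, hi)
        rest.validate("endpoint mixture remainder")
        return rest

    def _derived_probs(self) -> dict:
        """Conditional probabilities making the overall rates exact."""
        ks, p = discretized_pmf(self.options)
        cap = self.phase1_options.hi
        p_one = float(p[ks == 1].sum())
        p_forced = float(p[ks > cap].sum())  # more options than phase 1 can hold
        p_mid = float(p[(ks >= 2) & (ks <= cap)].sum())
        if self.p_phase2_addition < p_forced - 1e-12:
            raise ConfigError(
                f"p_phase2_addition = {self.p_phase2_addition} below the {p_forced:.3f} "
                "probability forced by options exceeding the phase-1 bound"
            )
        p_add_mid = 0.0 if p_mid == 0 else (self.p_phase2_addition - p_forced) / p_mid
        if p_add_mid > 1.0 + 1e-12:
            raise ConfigError(
                f"p_phase2_addition = {self.p_phase2_addition} unreachable: "
                f"P(>=2 options) = {1 - p_one:.3f}"
            )
        p_no_add = 1.0 - self.p_phase2_addition
        p_f1_given_add = (
            1.0
            if self.p_phase2_addition == 0
            else (self.p_final_in_phase1 - p_no_add) / self.p_phase2_addition
        )
        if not -1e-12 <= p_f1_given_add <= 1.0 + 1e-12:
            raise ConfigError("p_final_in_phase1 incompatible with p_phase2_addition")
        return {
            "p_add_mid": min(max(p_add_mid, 0.0), 1.0),
            "p_f1_given_add": min(max(p_f1_given_add, 0.0), 1.0),
        }

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        out: dict = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            out[f.name] = dataclasses.asdict(value) if isinstance(value, CountSpec) else value
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {}
        for key, value in data.items():
            kwargs[key] = CountSpec(**value) if key in _COUNT_FIELDS else value
        return cls(**kwargs)

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        from pathlib import Path

        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# Single-case generation
# ---------------------------------------------------------------------------

_PHASE2_SOURCES = (CueSource.MHT, CueSource.PE, CueSource.ILT)
_PHASE2_SOURCE_P = (0.55, 0.25, 0.20)


def _sample_endpoint_mixture(
    spec: CountSpec, p_extreme: float, top: bool, rng: np.random.Generator
) -> int:
    extreme = spec.hi if top else spec.lo
    if p_extreme >= 1.0 or rng.random() < p_extreme:
        return extreme
    rest = GeneratorConfig._rest_spec(spec, p_extreme, top)
    return sample_count(rest, rng)


def _interp_levels(start: int, end: int, k: int) -> List[int]:
    """k levels stepping monotonically from start towards end, ending at end."""
    return [int(round(start + (end - start) * j / k)) for j in range(1, k + 1)]


def _tristate(rng: np.random.Generator, p_yes: float) -> TriState:
    return TriState.YES if rng.random() < p_yes else TriState.NO


def generate_case(
    config: GeneratorConfig, rng: np.random.Generator, case_id: str = "case-00001"
) -> DecisionProcessMatrix:
    """Generate one valid, three-phase-conforming case.

    The emitted case has exactly one final diagnosis; every other option
    is excluded during the verification phase.  Confidence trajectories
    interpolate monotonically in scale steps between the sampled initial
    and terminal ratings.
    """
    config.validate()
    derived = config._derived_probs()

    n_opt = sample_count(config.options, rng)
    n_cue = sample_count(config.cues, rng)

    # phase-2 additions: options that cannot fit in phase 1 force additions;
    # single-option cases cannot have any; the middle is Bernoulli with the
    # conditional probability that keeps the overall rate exact.
    cap = config.phase1_options.hi
    if n_opt == 1:
        add = False
    elif n_opt > cap:
        add = True
    else:
        add = rng.random() < derived["p_add_mid"]
    if add:
        n1_opt = _sample_restricted(config.phase1_options, rng, 1, min(cap, n_opt - 1))
    else:
        n1_opt = n_opt
    n_added = n_opt - n1_opt

    n1_cue = _sample_restricted(config.phase1_cues, rng, 1, min(config.phase1_cues.hi, n_cue - 1))
    n2_cue = n_cue - n1_cue

    # which option is the final diagnosis
    final_in_p1 = True if not add else rng.random() < derived["p_f1_given_add"]
    if final_in_p1:
        final_idx = int(rng.integers(0, n1_opt))
    else:
        final_idx = n1_opt + int(rng.integers(0, n_added))

    # endpoint ratings per option; initial is drawn from its calibrated
    # marginal restricted to the trajectory's direction
    terminals: List[int] = []
    initials: List[int] = []
    for i in range(n_opt):
        if i == final_idx:
            term = _sample_endpoint_mixture(config.final_confidence, config.p_final_rated_max, True, rng)
            init = _sample_restricted(
                config.initial_confidence, rng, config.initial_confidence.lo, min(config.initial_confidence.hi, term)
            )
        else:
            term = _sample_endpoint_mixture(config.excluded_confidence, config.p_excluded_rated_min, False, rng)
            init = _sample_restricted(
                config.initial_confidence, rng, max(config.initial_confidence.lo, term), config.initial_confidence.hi
            )
        terminals.append(term)
        initials.append(init)

    # phase-2 schedule: insertion cue of each added option, number of ratings
    # per option and the cue each rating responds to
    insert_at = [int(rng.integers(1, n2_cue + 1)) for _ in range(n_added)]
    max_r = min(config.max_phase2_ratings, n2_cue)
    schedule: Dict[int, List[int]] = {j: [] for j in range(1, n2_cue + 1)}  # cue -> option indices
    n_ratings: List[int] = []
    for i in range(n_opt):
        start = 1 if i < n1_opt else insert_at[i - n1_opt]
        r = int(rng.integers(1, max_r + 1))
        positions = np.sort(rng.integers(start, n2_cue + 1, size=r))
        n_ratings.append(r)
        for pos in positions:
            schedule[int(pos)].append(i)

    # ------------------------------------------------------------------
    # assemble the event log
    cue_sources = [CueSource.MHT] * n1_cue + [
        _PHASE2_SOURCES[rng.choice(len(_PHASE2_SOURCES), p=_PHASE2_SOURCE_P)] for _ in range(n2_cue)
    ]
    cues = [Cue(f"c{j + 1:02d}", f"cue {j + 1:02d}", cue_sources[j]) for j in range(n_cue)]
    outcomes = [Outcome.FINAL if i == final_idx else Outcome.EXCLUDED for i in range(n_opt)]
    options = [OptionTrack(f"o{i + 1}", f"option {i + 1}", outcomes[i]) for i in range(n_opt)]

    units: List[Unit] = []
    idx = 0

    def emit(**kw) -> None:
        nonlocal idx
        idx += 1
        units.append(Unit(order_index=idx, **kw))

    # phase 1: cues, then each option with one rating cell per phase-1 cue
    for j in range(n1_cue):
        emit(kind=UnitKind.CUE, ref_id=cues[j].cue_id)
    for i in range(n1_opt):
        emit(kind=UnitKind.OPTION, ref_id=options[i].option_id)
        for j in range(n1_cue):
            emit(
                kind=UnitKind.CONFIDENCE,
                option_ref=options[i].option_id,
                cue_ref=cues[j].cue_id,
                level=initials[i],
            )

    # phase 2: cue stream with option insertions and scheduled ratings;
    # each option's ratings interpolate from its initial to its terminal,
    # the last one of an excluded option carrying the exclusion flag
    emitted_ratings = [0] * n_opt
    trajectories = [_interp_levels(initials[i], terminals[i], n_ratings[i]) for i in range(n_opt)]
    for j in range(1, n2_cue + 1):
        cue = cues[n1_cue + j - 1]
        emit(kind=UnitKind.CUE, ref_id=cue.cue_id)
        for i in range(n_added):
            if insert_at[i] == j:
                opt = options[n1_opt + i]
                emit(kind=UnitKind.OPTION, ref_id=opt.option_id)
                emit(kind=UnitKind.CONFIDENCE, option_ref=opt.option_id, cue_ref=cue.cue_id, level=initials[n1_opt + i])
        for i in schedule[j]:
            emitted_ratings[i] += 1
            last = emitted_ratings[i] == n_ratings[i]
            emit(
                kind=UnitKind.CONFIDENCE,
                option_ref=options[i].option_id,
                cue_ref=cue.cue_id,
                level=trajectories[i][emitted_ratings[i] - 1],
                is_exclusion=last and outcomes[i] is Outcome.EXCLUDED,
            )

    emit(kind=UnitKind.FINAL, option_ref=(options[final_idx].option_id,))

    experience = sample_count(config.experience_months, rng)
    case_exp = _tristate(rng, config.p_case_experience)
    metadata = CaseMetadata(
        case_id=case_id,
        resident_id=f"res-{case_id}",
        patient_age=int(rng.integers(18, 84)),
        patient_sex="F" if rng.random() < 0.51 else "M",
        time_pressure=_tristate(rng, config.p_time_pressure),
        stress=_tristate(rng, config.p_stress),
        case_experience=case_exp,
        similarity=sample_count(config.similarity, rng) if case_exp is TriState.YES else None,
        experience_months=experience,
    )
    # order the option registry by first appearance in the event log so the
    # case has a single canonical form across serialization dialects
    intro = {u.ref_id: u.order_index for u in units if u.kind is UnitKind.OPTION}
    options.sort(key=lambda o: intro[o.option_id])
    return DecisionProcessMatrix(metadata=metadata, units=tuple(units), cues=tuple(cues), options=tuple(options))


# ---------------------------------------------------------------------------
# Cohort generation with covariate correlation induction
# ---------------------------------------------------------------------------


def _case_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _normal_scores(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    jitter = rng.uniform(0, 1e-9, size=len(values))
    ranks = _sps.rankdata(np.asarray(values, dtype=float) + jitter, method="ordinal")
    return _sps.norm.ppf((ranks - 0.375) / (len(values) + 0.25))  # Blom scores


def _rank_match(
    values: np.ndarray,
    anchor: np.ndarray,
    target: float,
    rng: np.random.Generator,
    measure,
    max_iter: int = 10,
    tol: float = 0.01,
) -> np.ndarray:
    """Reorder *values* against *anchor* so measure(values, anchor) ~ target.

    Iman-Conover-style: build latent scores correlated with the anchor's
    normal scores and assign the sorted values by the latent ranks; the
    latent correlation is adjusted iteratively to compensate for
    attenuation by ties and discreteness.
    """
    n = len(values)
    if n < 3 or np.all(anchor == anchor[0]) or np.all(values == values[0]):
        return values
    z = _normal_scores(anchor, rng)
    eps = rng.standard_normal(n)
    values_sorted = np.sort(values)
    rho = float(np.clip(target, -0.99, 0.99))
    best = values.copy()
    best_gap = np.inf
    for _ in range(max_iter):
        w = rho * z + sqrt(max(0.0, 1.0 - rho * rho)) * eps
        out = np.empty(n, dtype=values.dtype)
        out[np.argsort(w)] = values_sorted
        realized = measure(out, anchor)
        gap = abs(realized - target)
        if gap < best_gap:
            best, best_gap = out, gap
        if gap < tol:
            break
        rho = float(np.clip(rho + (target - realized), -0.99, 0.99))
    return best


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1])


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    return _pearson(_sps.rankdata(x), _sps.rankdata(y))


def generate_cohort(
    config: GeneratorConfig, seed: Optional[int] = None
) -> Tuple[List[DecisionProcessMatrix], dict]:
    """Generate ``config.n_cases`` cases plus a provenance record.

    After the cases are drawn, the contextual covariates are reordered
    across cases (rank matching) so that experience correlates with the
    phase-2 cue count and similarity with the final-diagnosis confidence
    at their configured targets; the covariate marginals are untouched.
    """
    config.validate()
    root_seed = config.seed if seed is None else seed
    n = config.n_cases
    cases = [generate_case(config, _case_rng(root_seed, i), case_id=f"case-{i + 1:05d}") for i in range(n)]

    if n >= 3:
        from .core import terminal_confidence
        from .segmentation import phase_composition, segment

        rng = _case_rng(root_seed, 1 << 20)  # cohort-level stream
        phase2_cues = np.array(
            [phase_composition(c, segment(c)).phase2_cues for c in cases], dtype=float
        )
        experience = np.array([c.metadata.experience_months for c in cases], dtype=int)
        experience = _rank_match(
            experience, phase2_cues, config.r_experience_phase2_cues, rng, _pearson
        )

        final_conf = np.array(
            [terminal_confidence(c, c.final_option_ids()[0]).value for c in cases], dtype=float
        )
        has_exp = np.array([c.metadata.case_experience is TriState.YES for c in cases])
        similarity = np.array(
            [c.metadata.similarity if c.metadata.similarity is not None else 0 for c in cases], dtype=int
        )
        if has_exp.sum() >= 3:
            similarity_yes = _rank_match(
                similarity[has_exp],
                final_conf[has_exp],
                config.rs_similarity_final_confidence,
                rng,
                _spearman,
            )
            similarity[np.flatnonzero(has_exp)] = similarity_yes

        rebuilt = []
        for i, c in enumerate(cases):
            md = dataclasses.replace(
                c.metadata,
                experience_months=int(experience[i]),
                similarity=int(similarity[i]) if has_exp[i] else None,
            )
            rebuilt.append(dataclasses.replace(c, metadata=md))
        cases = rebuilt

    provenance = {
        "generator": "dpmkit.synthetic",
        "seed": root_seed,
        "n_cases": n,
        "config": config.to_dict(),
    }
    return cases, provenance


# ---------------------------------------------------------------------------
# Expert re-rater simulation (for agreement analytics)
# ---------------------------------------------------------------------------

#: Discrepancy distribution of expert minus resident rating, in scale
#: steps.  Chosen to reproduce the published agreement profile: perfect
#: match 33.3%, within one step 54.9%, two steps 11.8%, with the expert
#: underconfident (negative) in 47.1% and overconfident in 19.6% of
#: cases; the remaining one degree of freedom (the +2 share) is fixed at 4%.
DEFAULT_DISCREPANCY = {-2: 0.078, -1: 0.393, 0: 0.333, +1: 0.156, +2: 0.040}


def generate_rater_pairs(
    cases: Sequence[DecisionProcessMatrix],
    rng: np.random.Generator,
    p_concordant: float = 51 / 55,
    discrepancy: Optional[Dict[int, float]] = None,
) -> list:
    """Simulate an expert re-rater over the cohort's final diagnoses."""
    from .core import terminal_confidence

    discrepancy = DEFAULT_DISCREPANCY if discrepancy is None else discrepancy
    deltas = np.array(sorted(discrepancy))
    probs = np.array([discrepancy[d] for d in deltas], dtype=float)
    probs = probs / probs.sum()
    pairs = []
    for c in cases:
        final_ids = c.final_option_ids()
        resident = terminal_confidence(c, final_ids[0])
        delta = int(rng.choice(deltas, p=probs))
        # reflect a step that would leave the scale instead of clipping it
        # to the bound: clipping would silently inflate the perfect-match
        # share whenever the resident rating sits at an extreme
        expert = resident.value + delta
        if not -4 <= expert <= 4:
            expert = resident.value - delta
        expert = int(np.clip(expert, -4, 4))
        pairs.append(
            _concordance.RaterPair(
                case_id=c.metadata.case_id,
                resident_final_confidence=resident,
                expert_final_confidence=ConfidenceLevel(expert),
                diagnosis_concordant=bool(rng.random() < p_concordant),
            )
        )
    return pairs
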