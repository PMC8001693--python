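"""Random censoring, penalty criteria, and the two experimental designs.

Censoring removes a cow's culling age (her codes are then truncated at
the last reported calving). The nested sub-scenarios censor 20/40/60/80%
of the base: each level keeps the previous level's censored cows and adds
a fresh uniform sample of the still-uncensored ones.

The three penalty criteria replace a censored culling age with an imputed
one anchored at the last reported calving:

  m1: culled one year after the last reported calving, all cows;
  m2: cows older than nine years culled one year after the last calving,
      younger cows stay censored;
  m3: older than nine years culled one year after, younger cows two years
      after, the last calving.

Two designs remove the confounding between dataset size and censoring:
D1 keeps a fixed pool of uncensored cows and adds level% of that pool as
censored/penalized cows; D2 keeps the total fixed and censors level% of it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .datatypes import ConfigurationError, CowHistory, ScenarioSpec

__all__ = ["CensorAssignment", "assign_censoring", "censor_history",
           "penalize_history", "reference_age", "build_design", "design_counts"]

logger = logging.getLogger(__name__)

CENSOR_FRACTIONS = (0.2, 0.4, 0.6, 0.8)
AGE_THRESHOLD_YEARS = 9
MAX_CULLING_AGE = 20


@dataclass(frozen=True)
class CensorAssignment:
    """Nested censored-cow sets per replicate: S20 < S40 < S60 < S80."""

    sets: dict  # level -> frozenset of cow ids
    base_count: int
    seed: int

    def censored_at(self, level: int) -> frozenset:
        if level == 0:
            return frozenset()
        return self.sets[level]

    def __post_init__(self):
        prev: frozenset = frozenset()
        for lvl in (20, 40, 60, 80):
            cur = self.sets[lvl]
            if not prev <= cur:
                raise ValueError(f"censored sets not nested at level {lvl}")
            prev = cur


def assign_censoring(cows, seed: int, base_count: int | None = None) -> CensorAssignment:
    """Draw the nested 20/40/60/80% censored sets from ``cows``.

    ``base_count`` is the count whose percentages define the set sizes
    (defaults to len(cows); design D1 passes its uncensored-pool size).
    Sizes are rounded to the nearest integer.
    """
    ids = sorted(int(c.cow) if isinstance(c, CowHistory) else int(c) for c in cows)
    n = len(ids)
    if n < 5:
        raise ConfigurationError(f"need at least 5 cows to censor, got {n}")
    base = n if base_count is None else base_count
    sizes = [int(round(f * base)) for f in CENSOR_FRACTIONS]
    if sizes[-1] > n:
        raise ConfigurationError(
            f"cannot censor {sizes[-1]} of {n} cows (80% of base {base})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(ids)  # one permutation => nesting by prefix
    sets = {lvl: frozenset(int(x) for x in order[:size])
            for lvl, size in zip((20, 40, 60, 80), sizes)}
    return CensorAssignment(sets=sets, base_count=base, seed=seed)


def censor_history(history: CowHistory) -> CowHistory:
    """Remove the culling age; calving records are kept."""
    if history.censoring_state != "uncensored":
        raise ValueError(f"cow {history.cow} is already {history.censoring_state}")
    return replace(history, culling_age=None, censoring_state="censored")


def reference_age(history: CowHistory, evaluation_year: int,
                  source: str = "evaluation_year") -> int:
    """The 'cow's age' the nine-year penalty threshold is compared against."""
    if source == "evaluation_year":
        return evaluation_year - history.birth_year
    if source == "last_calving":
        if history.last_calving_age is None:
            raise ValueError(f"cow {history.cow}: no calving to anchor reference age")
        return history.last_calving_age
    raise ConfigurationError(f"unknown reference_age_source {source!r}")


def penalize_history(history: CowHistory, criterion: str,
                     reference_age: int) -> CowHistory:
    """Apply one penalty criterion to a censored cow."""
    if not history.is_censored:
        raise ValueError(f"cow {history.cow} is not censored; nothing to penalize")
    if criterion not in ("m1", "m2", "m3"):
        raise ValueError(f"criterion must be m1, m2 or m3, got {criterion!r}")
    last = history.last_calving_age
    if last is None:
        raise ValueError(f"cow {history.cow}: censored with no calving record; "
                         "no anchor for the penalty")
    old = reference_age > AGE_THRESHOLD_YEARS
    if criterion == "m1":
        years_after = 1
    elif criterion == "m2":
        if not old:
            return history  # younger cows keep their censored (missing) records
        years_after = 1
    else:  # m3
        years_after = 1 if old else 2
    imputed = last + years_after
    if imputed > MAX_CULLING_AGE:
        logger.warning("cow %s: imputed culling age %d capped at %d",
                       history.cow, imputed, MAX_CULLING_AGE)
        imputed = MAX_CULLING_AGE
    return replace(history, culling_age=imputed,
                   censoring_state=f"penalized-{criterion}")


def design_counts(design: str, level: int, pool: int) -> dict:
    """Cow counts implied by a design at a censoring level.

    For D1 ``pool`` is the fixed uncensored count U (total = U + level%*U);
    for D2 it is the fixed total N (censored = level%*N).
    """
    if design == "D1_fixed_uncensored":
        n_cen = int(round(level / 100 * pool))
        return {"uncensored": pool, "censored": n_cen, "total": pool + n_cen}
    if design == "D2_fixed_total":
        n_cen = int(round(level / 100 * pool))
        return {"uncensored": pool - n_cen, "censored": n_cen, "total": pool}
    raise ConfigurationError(f"unknown design {design!r}")


@dataclass
class ScenarioDataset:
    """One analysis dataset plus its manifest."""

    histories: list
    spec: ScenarioSpec
    censored_ids: frozenset
    manifest: dict


def build_design(cows, assignment: CensorAssignment, spec: ScenarioSpec,
                 pool_ids, evaluation_year: int) -> ScenarioDataset:
    """Assemble the analysis dataset of one scenario cell.

    ``pool_ids``: for D1 the fixed uncensored pool (the assignment must
    have been drawn from the remaining cows with base_count=len(pool_ids));
    for D2 the full fixed total (the assignment drawn from it).
    Treatment is applied to the censored set of the scenario's level.
    """
    by_id = {h.cow: h for h in cows}
    pool_ids = frozenset(int(i) for i in pool_ids)
    cen_ids = assignment.censored_at(spec.level)
    counts = design_counts(spec.design, spec.level, len(pool_ids))
    if len(cen_ids) != counts["censored"]:
        raise ConfigurationError(
            f"{spec.name}: assignment provides {len(cen_ids)} censored cows, "
            f"design requires {counts['censored']}")
    if spec.design == "D1_fixed_uncensored":
        keep_unc = pool_ids
        if cen_ids & pool_ids:
            raise ConfigurationError("D1 censored cows overlap the uncensored pool")
    else:
        keep_unc = pool_ids - cen_ids

    out = []
    n_missing_anchor = 0
    for cid in sorted(keep_unc):
        out.append(by_id[cid])
    for cid in sorted(cen_ids):
        h = censor_history(by_id[cid])
        if spec.treatment.startswith("PEN"):
            if h.last_calving_age is None:
                # no anchor: the cow stays censored (contributes nothing)
                n_missing_anchor += 1
            else:
                ref = reference_age(h, evaluation_year, spec.reference_age_source)
                h = penalize_history(h, spec.treatment[3:], ref)
        out.append(h)
    if n_missing_anchor:
        logger.warning("%s: %d censored cows had no calving anchor and stay censored",
                       spec.name, n_missing_anchor)
    manifest = {"scenario": spec.name, "design": spec.design, "level": spec.level,
                "treatment": spec.treatment, "replicate": spec.replicate,
                "seed": assignment.seed, "evaluation_year": evaluation_year,
                **counts, "censored_no_anchor": n_missing_anchor}
    return ScenarioDataset(histories=out, spec=spec,
                           censored_ids=frozenset(cen_ids), manifest=manifest)
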