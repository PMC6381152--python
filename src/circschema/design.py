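"""Synthetic two-group schema-consolidation experiment.

Emulates the continuous-report location-memory design: two groups of
participants each learn items from two relevant categories whose locations
cluster in category-specific 90-degree arcs of an invisible circle (the
location schemas), plus two irrelevant filler categories.  Phases:

* **IS**  — Initial Study, day 1, both relevant categories, original schemas.
* **NL1/NL2** — New Learning on day 1 / day 2.  The *relevant* NL phase
  (NL1 for the no-consolidation group, NL2 for the consolidation group)
  introduces new items of the relevant categories with one category's schema
  mean shifted 90 degrees clockwise (the inconsistent category); the other NL
  phase presents the irrelevant categories.
* **FT**  — Final Test, 48 h after the relevant NL phase: every studied item
  is tested a second time.

One row of the trial table is one continuous-report *test* trial.  Items
studied in the relevant NL phase are the *critical items*: they were learned
exactly 48 h before the Final Test and carry ``is_critical=True`` (both their
NL test row and their FT re-test row).

Responses are simulated from the generative mixture the analysis assumes:
with cell-specific probabilities the response is a von Mises draw around the
target, a von Mises draw around the category's *original* schema mean, or a
uniform guess.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .circular import circ_dist, wrap_circle

__all__ = [
    "GROUPS",
    "PHASES",
    "DesignConfig",
    "CellParams",
    "GenerativeParams",
    "default_generative_params",
    "build_design",
    "sample_target",
    "simulate_responses",
    "simulate_experiment",
    "simulate_cell_trials",
    "phase_kind",
    "relevant_nl_phase",
]

GROUPS = ("no_consolidation", "consolidation")
PHASES = ("IS", "NL1", "NL2", "FT")

#: trial-table column order; the on-disk contract with the analysis modules
TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "phase",
    "block",
    "category",
    "category_role",
    "quadrant",
    "is_critical",
    "target",
    "response",
    "schema_mean_current",
    "schema_mean_original",
]


def phase_kind(phase: str) -> str:
    """Collapse NL1/NL2 to the phase kind 'NL' (IS and FT map to themselves)."""
    return "NL" if phase in ("NL1", "NL2") else phase


def relevant_nl_phase(group: str) -> str:
    """The New Learning phase in which a group studies its relevant categories."""
    if group == "no_consolidation":
        return "NL1"
    if group == "consolidation":
        return "NL2"
    raise ValueError(f"unknown group {group!r}")


@dataclass(frozen=True)
class DesignConfig:
    """Structural parameters of the experiment.

    Defaults reproduce the published design: 2 groups x 32 participants,
    4 categories in quadrants 90 degrees apart, 28-trial blocks with 22
    inside-quadrant and 6 outside-quadrant trials, 4 blocks per study phase,
    a 90-degree clockwise schema shift for the inconsistent category at New
    Learning, and a Final Test of all 336 studied items in 6 blocks of 56.
    """

    n_per_group: int = 32
    categories: Tuple[str, ...] = ("animals", "food", "clothes", "furniture")
    quadrant_centres: Tuple[float, ...] = (45.0, 135.0, 225.0, 315.0)
    trials_per_block: int = 28
    inside_per_block: int = 22
    outside_per_block: int = 6
    blocks_IS: int = 4
    blocks_NL: int = 4
    ft_blocks: int = 6
    shift_deg: float = 90.0  # clockwise shift of the inconsistent schema at NL
    inside_halfwidth_deg: float = 45.0
    outside_margin_deg: float = 30.0
    miss_prob: float = 0.0  # probability a response times out (missing)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 0:
            raise ValueError("n_per_group must be >= 0")
        if len(self.categories) != 4 or len(set(self.categories)) != 4:
            raise ValueError("exactly 4 distinct categories are required")
        if len(self.quadrant_centres) != 4:
            raise ValueError("exactly 4 quadrant centres are required")
        if self.inside_per_block + self.outside_per_block != self.trials_per_block:
            raise ValueError(
                "inside_per_block + outside_per_block must equal trials_per_block"
            )
        # two intermixed categories per study block, each with its own quota
        for name in ("trials_per_block", "inside_per_block", "outside_per_block"):
            if getattr(self, name) % 2 != 0:
                raise ValueError(f"{name} must be even (two categories per block)")
        centres = np.asarray(self.quadrant_centres, dtype=float)
        for i in range(4):
            for j in range(i + 1, 4):
                if abs(circ_dist(centres[i], centres[j])) < 90.0 - 1e-9:
                    raise ValueError("quadrant centres must be pairwise >= 90 degrees apart")
        n_study = (self.blocks_IS + 2 * self.blocks_NL) * self.trials_per_block
        if self.ft_blocks <= 0 or n_study % self.ft_blocks != 0:
            raise ValueError("total studied trials must divide evenly into ft_blocks")
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must be in [0, 1]")

    @property
    def n_study_trials(self) -> int:
        """Studied (= FT-retested) items per participant; 336 under defaults."""
        return (self.blocks_IS + 2 * self.blocks_NL) * self.trials_per_block

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class CellParams:
    """Generative mixture weights and concentration for one design cell."""

    p_target: float
    p_schema_old: float
    p_guess: float
    kappa: float

    def __post_init__(self):
        w = (self.p_target, self.p_schema_old, self.p_guess)
        if any(p < 0 for p in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must be >= 0 and sum to 1, got {w}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


class GenerativeParams:
    """Per-cell generative parameters, keyed by (group, category_role, phase kind).

    Phase kind is one of ``IS``, ``NL``, ``FT`` (NL1 and NL2 share a cell).
    A trial whose cell is missing raises ``KeyError`` — no silent defaults.
    """

    def __init__(self, cells: Mapping[Tuple[str, str, str], CellParams]):
        self.cells: Dict[Tuple[str, str, str], CellParams] = dict(cells)

    def for_cell(self, group: str, category_role: str, phase: str) -> CellParams:
        key = (group, category_role, phase_kind(phase))
        try:
            return self.cells[key]
        except KeyError:
            raise KeyError(
                f"no generative parameters for cell {key}; "
                "every (group, category_role, phase-kind) present in the design "
                "must be specified explicitly"
            ) from None

    def replace(self, group: str, category_role: str, kind: str, **changes) -> "GenerativeParams":
        cells = dict(self.cells)
        cells[(group, category_role, kind)] = dataclasses.replace(
            cells[(group, category_role, kind)], **changes
        )
        return GenerativeParams(cells)

    def to_dict(self) -> dict:
        return {"/".join(k): dataclasses.asdict(v) for k, v in sorted(self.cells.items())}


def default_generative_params() -> GenerativeParams:
    """Study-condition defaults for the response-generating mixture.

    The old-schema weights at the critical cells are the published group-level
    attribution means: 0.49 (no-consolidation) vs 0.32 (consolidation) for
    inconsistent-category items at Final Test, and 0.03 vs 0.00 at the
    immediate New Learning test.  Remaining values (guess rates, schema pull
    for consistent categories, concentrations) are stated and motivated in the
    methods note: immediate tests are precise (kappa 25, 5% guesses), the 48 h
    Final Test is noisier (kappa 15, 10% guesses), and a modest schema pull is
    present from Initial Study onward so that initial schema strength is a
    meaningful individual-difference measure.
    """
    nc, cg = GROUPS
    cells: Dict[Tuple[str, str, str], CellParams] = {}
    for g in (nc, cg):
        for role in ("consistent", "inconsistent"):
            cells[(g, role, "IS")] = CellParams(0.85, 0.10, 0.05, 25.0)
        cells[(g, "consistent", "NL")] = CellParams(0.87, 0.08, 0.05, 25.0)
        cells[(g, "irrelevant", "NL")] = CellParams(0.87, 0.08, 0.05, 25.0)
        cells[(g, "consistent", "FT")] = CellParams(0.70, 0.20, 0.10, 15.0)
        cells[(g, "irrelevant", "FT")] = CellParams(0.70, 0.20, 0.10, 15.0)
    cells[(nc, "inconsistent", "NL")] = CellParams(0.92, 0.03, 0.05, 25.0)
    cells[(cg, "inconsistent", "NL")] = CellParams(0.95, 0.00, 0.05, 25.0)
    cells[(nc, "inconsistent", "FT")] = CellParams(0.41, 0.49, 0.10, 15.0)
    cells[(cg, "inconsistent", "FT")] = CellParams(0.58, 0.32, 0.10, 15.0)
    return GenerativeParams(cells)


def sample_target(
    schema_mean: float,
    quadrant: str,
    rng: np.random.Generator,
    inside_halfwidth: float = 45.0,
    outside_margin: float = 30.0,
) -> float:
    """Draw one target location for a trial of the given quadrant type.

    Inside-quadrant targets are uniform on ``[mean - 45, mean + 45]``;
    outside-quadrant targets are uniform on the complement of
    ``[mean - 75, mean + 75]`` (the quadrant plus a 30-degree buffer), i.e. a
    210-degree arc under defaults.  Uniformity on the allowed arcs is the
    maximum-entropy choice; only the margin itself is part of the design.
    """
    if quadrant == "inside":
        offset = rng.uniform(-inside_halfwidth, inside_halfwidth)
    elif quadrant == "outside":
        excluded = inside_halfwidth + outside_margin
        offset = excluded + rng.uniform(0.0, 360.0 - 2.0 * excluded)
    else:
        raise ValueError(f"quadrant must be 'inside' or 'outside', got {quadrant!r}")
    return float(wrap_circle(schema_mean + offset))


def _participant_rows(config: DesignConfig, pid: str, group: str, rng: np.random.Generator) -> list:
    cats = list(config.categories)
    centres = rng.permutation(np.asarray(config.quadrant_centres, dtype=float))
    original = {c: float(m) for c, m in zip(cats, centres)}
    # one relevant category from each pair (natural / human-made), counterbalanced
    relevant = [cats[rng.integers(0, 2)], cats[2 + rng.integers(0, 2)]]
    inconsistent = relevant[rng.integers(0, 2)]
    irrelevant = [c for c in cats if c not in relevant]
    shifted = {c: m for c, m in original.items()}
    shifted[inconsistent] = float(wrap_circle(original[inconsistent] - config.shift_deg))

    def role(cat: str) -> str:
        if cat == inconsistent:
            return "inconsistent"
        return "consistent" if cat in relevant else "irrelevant"

    nl_rel = relevant_nl_phase(group)
    nl_irr = "NL2" if nl_rel == "NL1" else "NL1"
    phase_plan = [
        ("IS", config.blocks_IS, relevant, original, False),
        (nl_rel, config.blocks_NL, relevant, shifted, True),
        (nl_irr, config.blocks_NL, irrelevant, original, False),
    ]
    phase_plan.sort(key=lambda p: PHASES.index(p[0]))

    n_in = config.inside_per_block // 2  # per category per block
    n_out = config.outside_per_block // 2
    rows = []
    for phase, n_blocks, phase_cats, means, critical in phase_plan:
        for block in range(n_blocks):
            block_rows = []
            for cat in phase_cats:
                mean = means[cat]
                quadrants = ["inside"] * n_in + ["outside"] * n_out
                for quadrant in quadrants:
                    target = sample_target(
                        mean,
                        quadrant,
                        rng,
                        config.inside_halfwidth_deg,
                        config.outside_margin_deg,
                    )
                    block_rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "phase": phase,
                            "block": block,
                            "category": cat,
                            "category_role": role(cat),
                            "quadrant": quadrant,
                            "is_critical": critical,
                            "target": target,
                            "response": np.nan,
                            "schema_mean_current": mean,
                            "schema_mean_original": original[cat],
                        }
                    )
            order = rng.permutation(len(block_rows))
            rows.extend(block_rows[i] for i in order)

    # Final Test: every studied item re-tested, shuffled into ft_blocks blocks
    studied = [dict(r) for r in rows]
    order = rng.permutation(len(studied))
    block_size = config.n_study_trials // config.ft_blocks
    for slot, i in enumerate(order):
        r = studied[i]
        r["phase"] = "FT"
        r["block"] = slot // block_size
        rows.append(r)
    return rows


def build_design(config: DesignConfig | None = None) -> pd.DataFrame:
    """Build the full trial table for both groups, responses left missing.

    Every participant gets an independent child RNG stream derived from
    ``config.seed`` and the participant's index, so any single participant's
    design is reproducible in isolation.
    """
    config = config or DesignConfig()
    rows: list = []
    for gi, group in enumerate(GROUPS):
        prefix = "nc" if group == "no_consolidation" else "co"
        for i in range(config.n_per_group):
            pidx = gi * config.n_per_group + i
            rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0, pidx)))
            rows.extend(_participant_rows(config, f"{prefix}{i:02d}", group, rng))
    if not rows:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _simulate_block(
    targets: np.ndarray,
    schema_old: np.ndarray,
    cell: CellParams,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(targets)
    comp = rng.choice(3, size=n, p=[cell.p_target, cell.p_schema_old, cell.p_guess])
    kappa_rad = cell.kappa
    noise = np.degrees(rng.vonmises(0.0, kappa_rad, size=n)) if kappa_rad > 0 else rng.uniform(
        -180.0, 180.0, size=n
    )
    resp = np.where(
        comp == 0,
        targets + noise,
        np.where(comp == 1, schema_old + noise, rng.uniform(0.0, 360.0, size=n)),
    )
    return wrap_circle(resp)


def simulate_responses(
    trials: pd.DataFrame,
    params: GenerativeParams,
    seed: int | None = None,
    miss_prob: float = 0.0,
) -> pd.DataFrame:
    """Fill in responses from the generative mixture; returns a new frame.

    Per trial, a component is drawn by the cell's weights: *target* (von Mises
    around the target), *old schema* (von Mises around the category's original
    schema mean), or *guess* (uniform on the circle).  With probability
    ``miss_prob`` the response is recorded as missing (a response timeout).
    Participants are simulated on independent child streams keyed by their
    position in the table, mirroring :func:`build_design`.
    """
    out = trials.copy()
    if len(out) == 0:
        return out
    # validate cell coverage up front: a missing cell is an error, not a default
    cells = out[["group", "category_role", "phase"]].drop_duplicates()
    for g, role, phase in cells.itertuples(index=False):
        params.for_cell(g, role, phase)

    responses = np.full(len(out), np.nan)
    for pidx, (_, part) in enumerate(out.groupby("participant_id", sort=True)):
        rng = np.random.default_rng(
            np.random.SeedSequence(0 if seed is None else seed, spawn_key=(1, pidx))
        )
        for (g, role, phase), sub in part.groupby(["group", "category_role", "phase"], sort=True):
            cell = params.for_cell(g, role, phase)
            idx = out.index.get_indexer(sub.index)
            responses[idx] = _simulate_block(
                sub["target"].to_numpy(float),
                sub["schema_mean_original"].to_numpy(float),
                cell,
                rng,
            )
        if miss_prob > 0:
            idx = out.index.get_indexer(part.index)
            missing = rng.uniform(size=len(idx)) < miss_prob
            responses[idx[missing]] = np.nan
    out["response"] = responses
    return out


def simulate_experiment(
    config: DesignConfig | None = None,
    params: GenerativeParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Build the design and simulate all responses in one call."""
    config = config or DesignConfig()
    params = params or default_generative_params()
    seed = config.seed if seed is None else seed
    if seed != config.seed:
        config = dataclasses.replace(config, seed=seed)
    trials = build_design(config)
    return simulate_responses(trials, params, seed=seed, miss_prob=config.miss_prob)


def simulate_cell_trials(
    n_participants: int,
    trials_per_participant: int,
    cell: CellParams,
    seed: int | None = None,
    schema_mean: float = 90.0,
    schema_offset: float = 90.0,
    group: str = "no_consolidation",
    phase: str = "FT",
    category_role: str = "inconsistent",
    inside_halfwidth: float = 45.0,
) -> pd.DataFrame:
    """Simulate a standalone set of critical-style trials from one design cell.

    A lightweight generator for recovery and permutation studies that only
    need the critical trials: targets are uniform inside the current schema
    quadrant (centre ``schema_mean``), the original (old) schema mean sits
    ``schema_offset`` degrees counter-clockwise of the current one (i.e. the
    current mean is the old one shifted clockwise), and responses follow the
    cell's target / old-schema / guess mixture.
    """
    rng = np.random.default_rng(seed)
    n = n_participants * trials_per_participant
    targets = wrap_circle(schema_mean + rng.uniform(-inside_halfwidth, inside_halfwidth, size=n))
    old_mean = float(wrap_circle(schema_mean + schema_offset))
    responses = _simulate_block(targets, np.full(n, old_mean), cell, rng)
    return pd.DataFrame(
        {
            "participant_id": np.repeat(
                [f"p{i:03d}" for i in range(n_participants)], trials_per_participant
            ),
            "group": group,
            "phase": phase,
            "block": 0,
            "category": "animals",
            "category_role": category_role,
            "quadrant": "inside",
            "is_critical": True,
            "target": targets,
            "response": responses,
            "schema_mean_current": float(schema_mean),
            "schema_mean_original": old_mean,
        },
        columns=TRIAL_COLUMNS,
    )
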