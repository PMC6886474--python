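"""Synthetic labeled datasets and screening libraries with planted structure.

Emulates the statistical shape of a patent-actives + decoys QSAR table:
class-informative columns with a configurable effect size, near-duplicate
(redundant) columns, zero-variance columns, and pure-noise columns, in a
configurable mix of binary fingerprint bits and continuous descriptors.
Ground-truth column roles and planted-active row flags are carried along so
downstream filters, selectors, and screens can be scored against the truth.

Generative model (per row of class y in {0 inactive, 1 active}):

* continuous informative  ~ Normal(effect_size * y, 1)
* binary informative      ~ Bernoulli(0.3 + gap * y), gap = min(0.2*effect, 0.6)
* noise                   ~ Normal(0, 1) or Bernoulli(0.3), class-blind
* redundant               = copy of a random informative column, each entry
                            independently resampled from that column's
                            marginal with probability ``redundancy_noise``
* zero-variance           = constant

Simulated IC50s for active rows are log-uniform on [0.05, 11.4] uM so the
canonical activity cutoffs (4/3/2/1/11.4) all partition the actives
nontrivially; decoy rows carry no IC50.

RNG streams are split per column block (informative / redundant corruption
/ zero-variance / noise / ic50), so e.g. adding noise columns never
perturbs the informative block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, SchemaError
from .table import ACTIVE, ASSAYED, BINARY, CONTINUOUS, DECOY, INACTIVE, FeatureTable

BASE_BIT_RATE = 0.3
IC50_RANGE_UM = (0.05, 11.4)

_LIBRARY_STREAM_TAG = 0x5C12EE  # decorrelates library rows from training rows


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs for one synthetic dataset."""

    n_active: int = 266
    n_inactive: int = 136
    n_informative: int = 10
    n_redundant: int = 5
    n_zero_variance: int = 5
    n_noise: int = 20
    frac_binary: float = 0.5
    effect_size: float = 1.0
    redundancy_noise: float = 0.01
    seed: int = 0
    ic50_range_um: tuple = IC50_RANGE_UM

    def validate(self) -> None:
        for fld in (
            "n_active",
            "n_inactive",
            "n_informative",
            "n_redundant",
            "n_zero_variance",
            "n_noise",
        ):
            if getattr(self, fld) < 0:
                raise ConfigurationError(f"{fld} must be >= 0")
        if self.n_informative + self.n_redundant + self.n_zero_variance + self.n_noise < 1:
            raise ConfigurationError("total column count must be >= 1")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ConfigurationError(
                "n_redundant > 0 requires n_informative >= 1 (source columns)"
            )
        if not 0.0 <= self.frac_binary <= 1.0:
            raise ConfigurationError("frac_binary must lie in [0, 1]")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if not 0.0 <= self.redundancy_noise < 0.5:
            raise ConfigurationError("redundancy_noise must lie in [0, 0.5)")
        lo, hi = self.ic50_range_um
        if not 0 < lo < hi:
            raise ConfigurationError("ic50_range_um must satisfy 0 < lo < hi")


@dataclass
class GeneratedDataset:
    """A generated table plus the ground truth used to score the pipeline."""

    table: FeatureTable
    truth: pd.Series  # per column: informative | redundant-of:<col> | zero-variance | noise
    ic50: Optional[pd.Series] = None
    planted: Optional[pd.Series] = None  # screening libraries: per-row bool
    spec: Optional[SyntheticSpec] = field(default=None, compare=False)


# ----------------------------------------------------------------------
# column-structure plan, deterministic in spec.seed
def _binary_count(n: int, frac: float) -> int:
    return int(round(n * frac))


def _plan(spec: SyntheticSpec) -> dict:
    """Deterministic column layout shared by training and library draws."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    gap = min(0.2 * spec.effect_size, 0.6)

    inf_kinds = [
        BINARY if i < _binary_count(spec.n_informative, spec.frac_binary) else CONTINUOUS
        for i in range(spec.n_informative)
    ]
    noise_kinds = [
        BINARY if i < _binary_count(spec.n_noise, spec.frac_binary) else CONTINUOUS
        for i in range(spec.n_noise)
    ]
    zv_kinds = [
        BINARY if i < _binary_count(spec.n_zero_variance, spec.frac_binary) else CONTINUOUS
        for i in range(spec.n_zero_variance)
    ]
    # Redundant columns clone continuous sources when any exist: tau-a
    # between near-identical *binary* columns is bounded well below the
    # 0.9 redundancy cutoff (tied pairs count as neither concordant nor
    # discordant), so only continuous clones are detectable by the filter.
    cont_sources = [i for i, k in enumerate(inf_kinds) if k == CONTINUOUS]
    source_pool = np.asarray(cont_sources if cont_sources else range(spec.n_informative))
    red_sources = (
        source_pool[rng.integers(0, len(source_pool), size=spec.n_redundant)]
        if spec.n_redundant
        else np.array([], dtype=int)
    )
    zv_values = [
        0.0 if k == BINARY else float(rng.normal()) for k in zv_kinds
    ]
    return {
        "gap": gap,
        "inf_kinds": inf_kinds,
        "noise_kinds": noise_kinds,
        "zv_kinds": zv_kinds,
        "zv_values": zv_values,
        "red_sources": red_sources,
    }


def _draw_block(rng, kinds, y, effect, gap):
    """Class-conditional draws for one column block; shape (n, len(kinds))."""
    n = len(y)
    cols = np.empty((n, len(kinds)))
    for j, kind in enumerate(kinds):
        if kind == BINARY:
            p = BASE_BIT_RATE + gap * y
            cols[:, j] = (rng.random(n) < p).astype(float)
        else:
            cols[:, j] = rng.normal(0.0, 1.0, size=n) + effect * y
    return cols


def _materialize(spec: SyntheticSpec, y: np.ndarray, seed_seq) -> tuple:
    """Build the full feature matrix for rows of class vector ``y``."""
    plan = _plan(spec)
    ss_inf, ss_red, ss_noise = seed_seq.spawn(3)
    rng_inf = np.random.default_rng(ss_inf)
    rng_red = np.random.default_rng(ss_red)
    rng_noise = np.random.default_rng(ss_noise)

    inf = _draw_block(rng_inf, plan["inf_kinds"], y, spec.effect_size, plan["gap"])

    red = np.empty((len(y), spec.n_redundant))
    red_kinds = []
    for j, src in enumerate(plan["red_sources"]):
        kind = plan["inf_kinds"][src]
        red_kinds.append(kind)
        col = inf[:, src].copy()
        corrupt = rng_red.random(len(y)) < spec.redundancy_noise
        if corrupt.any():
            fresh = _draw_block(
                rng_red, [kind], y[corrupt], spec.effect_size, plan["gap"]
            )[:, 0]
            col[corrupt] = fresh
        red[:, j] = col

    zv = np.tile(np.asarray(plan["zv_values"]), (len(y), 1)) if spec.n_zero_variance else np.empty((len(y), 0))
    noise = _draw_block(rng_noise, plan["noise_kinds"], np.zeros_like(y), 0.0, 0.0)

    names, kinds, roles, blocks = [], [], [], []
    inf_names = [f"INF{i:03d}" for i in range(spec.n_informative)]
    for block, blk_names, blk_kinds, role in (
        (inf, inf_names, plan["inf_kinds"], ["informative"] * spec.n_informative),
        (
            red,
            [f"RED{i:03d}" for i in range(spec.n_redundant)],
            red_kinds,
            [f"redundant-of:{inf_names[s]}" for s in plan["red_sources"]],
        ),
        (
            zv,
            [f"ZV{i:03d}" for i in range(spec.n_zero_variance)],
            plan["zv_kinds"],
            ["zero-variance"] * spec.n_zero_variance,
        ),
        (
            noise,
            [f"NOISE{i:03d}" for i in range(spec.n_noise)],
            plan["noise_kinds"],
            ["noise"] * spec.n_noise,
        ),
    ):
        names.extend(blk_names)
        kinds.extend(blk_kinds)
        roles.extend(role)
        blocks.append(block)

    matrix = np.hstack(blocks)
    return matrix, names, kinds, roles


def generate_training_dataset(spec: SyntheticSpec) -> GeneratedDataset:
    """Labeled actives + decoys table with truth tags and simulated IC50s."""
    spec.validate()
    n = spec.n_active + spec.n_inactive
    y = np.concatenate([np.ones(spec.n_active, int), np.zeros(spec.n_inactive, int)])
    seed_seq = np.random.SeedSequence([spec.seed, 1])
    matrix, names, kinds, roles = _materialize(spec, y, seed_seq)

    row_ids = [f"CPD{i:05d}" for i in range(n)]
    rng_ic50 = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    lo, hi = spec.ic50_range_um
    ic50 = np.full(n, np.nan)
    ic50[: spec.n_active] = np.exp(
        rng_ic50.uniform(np.log(lo), np.log(hi), size=spec.n_active)
    )

    data = pd.DataFrame(matrix, index=row_ids, columns=names)
    table = FeatureTable(
        data=data,
        col_kind=pd.Series(kinds, index=names),
        labels=pd.Series(np.where(y == 1, ACTIVE, INACTIVE), index=row_ids),
        ic50=pd.Series(ic50, index=row_ids),
        source=pd.Series(np.where(y == 1, ASSAYED, DECOY), index=row_ids),
        name="synthetic-train",
    )
    return GeneratedDataset(
        table=table,
        truth=pd.Series(roles, index=names),
        ic50=table.ic50,
        spec=spec,
    )


def generate_screening_library(
    spec: SyntheticSpec,
    n_compounds: int,
    planted_active_fraction: float,
    training: Optional[GeneratedDataset] = None,
) -> GeneratedDataset:
    """Unlabeled library sharing the training schema, with planted actives.

    The planted-active count is ``round(n_compounds * fraction)`` (banker's
    rounding via :func:`round`); planted rows are drawn from the
    active-class distribution and scattered at seeded random positions.
    """
    spec.validate()
    if n_compounds < 1:
        raise ConfigurationError("n_compounds must be >= 1")
    if not 0.0 <= planted_active_fraction <= 1.0:
        raise ConfigurationError("planted_active_fraction must lie in [0, 1]")

    n_planted = int(round(n_compounds * planted_active_fraction))
    seed_seq = np.random.SeedSequence([spec.seed, _LIBRARY_STREAM_TAG])
    rng_pos = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    y = np.zeros(n_compounds, int)
    pos = rng_pos.choice(n_compounds, size=n_planted, replace=False)
    y[pos] = 1

    matrix, names, kinds, roles = _materialize(spec, y, seed_seq)
    if training is not None and list(training.table.data.columns) != names:
        raise SchemaError(
            "screening spec does not reproduce the training schema "
            "(column sets differ)"
        )

    row_ids = [f"LIB{i:07d}" for i in range(n_compounds)]
    data = pd.DataFrame(matrix, index=row_ids, columns=names)
    table = FeatureTable(
        data=data,
        col_kind=pd.Series(kinds, index=names),
        name="synthetic-library",
    )
    return GeneratedDataset(
        table=table,
        truth=pd.Series(roles, index=names),
        planted=pd.Series(y.astype(bool), index=row_ids),
        spec=spec,
    )
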