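"""Synthetic meta-analytic tables.

Emulates the structure of a study-level meta-analytic table: many small
studies of one true standardized effect, each observed with sampling error
of order ``1/sqrt(n)``.  The default is the one-sample (within-subject
scoring) design typical of the precognition literature the re-analysis
pipeline targets:

    d_obs = true_d + T(df = n - 1) / sqrt(n)

Two-group fixtures draw both group means with the calibration engine's
kernel, so their observed differences carry ``sqrt(2/n)``-scale noise.

What the generator does *not* emulate: publication bias, heterogeneous true
effects across studies, and reporting error — synthetic tables are ideal-world
draws around a single population effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ValidationError
from .meta import MetaStudyRecord

__all__ = ["FixtureConfig", "generate_meta_fixture"]


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of one synthetic study table.

    ``n_per_group`` is either a single per-group size shared by all studies
    or a sequence sampled from uniformly per study.  ``n_peer_reviewed``
    marks a random subset of studies as peer-reviewed (all of them when
    ``None``), mimicking tables that mix peer-reviewed and grey literature.
    """

    n_studies: int
    true_d: float
    n_per_group: int | Sequence[int] = 100
    one_sample: bool = True
    n_peer_reviewed: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValidationError("n_studies must be >= 1")
        if not math.isfinite(self.true_d):
            raise ValidationError("true_d must be finite")
        sizes = self._sizes()
        if any(n < 2 for n in sizes):
            raise ValidationError("per-group sizes must be >= 2")
        if self.n_peer_reviewed is not None and not (
            0 <= self.n_peer_reviewed <= self.n_studies
        ):
            raise ValidationError("n_peer_reviewed must be in [0, n_studies]")

    def _sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_per_group, int):
            return (self.n_per_group,)
        return tuple(int(n) for n in self.n_per_group)


def generate_meta_fixture(config: FixtureConfig) -> list[MetaStudyRecord]:
    """Draw a reproducible synthetic study table.

    All randomness flows through one generator seeded from ``config.seed``;
    the same config always yields the identical table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5F1D]))
    choices = config._sizes()
    records = []
    reviewed = np.ones(config.n_studies, dtype=bool)
    if config.n_peer_reviewed is not None:
        reviewed[:] = False
        idx = rng.permutation(config.n_studies)[: config.n_peer_reviewed]
        reviewed[idx] = True
    width = max(3, len(str(config.n_studies)))
    for i in range(config.n_studies):
        n = int(choices[rng.integers(len(choices))]) if len(choices) > 1 else choices[0]
        if config.one_sample:
            d_obs = config.true_d + rng.standard_t(n - 1) / math.sqrt(n)
            n1 = None
        else:
            noise0 = rng.standard_t(n - 1) / math.sqrt(n)
            noise1 = rng.standard_t(n - 1) / math.sqrt(n)
            d_obs = config.true_d + noise1 - noise0
            n1 = n
        records.append(
            MetaStudyRecord(
                study_id=f"S{i + 1:0{width}d}",
                n0=n,
                n1=n1,
                d_obs=float(d_obs),
                s=1.0,
                peer_reviewed=bool(reviewed[i]),
            )
        )
    return records
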