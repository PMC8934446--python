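"""Weight schemes and distance parameters.

Error weights encode the relative penalty of each error type; the platform
presets mirror the indel-biased error profiles of PacBio Sequel-like and
ONT MinION-like long reads (insertion-heavy vs deletion-heavy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class WeightScheme:
    """Per-error-type costs used by the weighted recurrence.

    ``w_sub`` is the mismatch cost K of the diagonal move.  A "prohibitive"
    substitution weight is any finite value exceeding the cost of the most
    expensive all-indel path for the strings at hand (``prohibitive`` builds
    one).
    """

    w_ins: float = 1.0
    w_del: float = 1.0
    w_sub: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w_ins", "w_del", "w_sub"):
            v = getattr(self, name)
            if not (v >= 0) or math.isinf(v) or math.isnan(v):
                raise ValueError(f"{name} must be a finite non-negative number, got {v!r}")

    @classmethod
    def unit(cls) -> "WeightScheme":
        return cls(1.0, 1.0, 1.0)

    @property
    def is_unit(self) -> bool:
        return self.w_ins == self.w_del == self.w_sub == 1.0

    def prohibitive_substitution(self, max_len: int) -> "WeightScheme":
        """Copy of this scheme whose substitution weight can never lie on an
        optimal path for strings up to ``max_len`` bases."""
        cap = (self.w_ins + self.w_del) * max_len + 1
        return WeightScheme(self.w_ins, self.w_del, cap)


#: Insertion-heavy profile measured on PacBio Sequel-like simulated reads.
PACBIO_WEIGHTS = WeightScheme(w_ins=1, w_del=2, w_sub=4)
#: Deletion-heavy profile measured on ONT MinION-like simulated reads.
NANOPORE_WEIGHTS = WeightScheme(w_ins=2, w_del=1, w_sub=4)


def frameshift_positions(length: int, fraction: float = 0.15) -> int:
    """Convert a percent-of-length frameshift allowance to whole positions.

    Rounds half up, because allowances are whole border positions.  The
    default allowance is 15 % of the sequence length.
    """
    if length < 0:
        raise ValueError("length must be non-negative")
    return int(math.floor(length * fraction + 0.5))


@dataclass(frozen=True)
class DistanceParams:
    """Bundle of clustering-metric parameters.

    tau
        Total expected/allowed error count between two related sequences.
    frameshift
        Tolerated border displacement (positions) due to up/downstream indels.
    weights
        Per-type error costs.
    weight_threshold
        Maximum cumulative error weight for two sequences to be linked.
    """

    tau: int = 3
    frameshift: int = 3
    weights: WeightScheme = field(default_factory=WeightScheme.unit)
    weight_threshold: float = 8.0

    def __post_init__(self) -> None:
        if self.tau < 0 or int(self.tau) != self.tau:
            raise ValueError("tau must be a non-negative integer")
        if self.frameshift < 0 or int(self.frameshift) != self.frameshift:
            raise ValueError("frameshift must be a non-negative integer")
        if not self.weight_threshold >= 0:
            raise ValueError("weight_threshold must be non-negative")

    @property
    def h(self) -> int:
        """Early-termination bound: tau + frameshift."""
        return int(self.tau) + int(self.frameshift)
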