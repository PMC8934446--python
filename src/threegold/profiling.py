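"""Error-profile characterisation between reference and experimental reads.

Long-read platforms have strongly type-biased error profiles (PacBio
Sequel-like chemistry is insertion-heavy, ONT MinION-like chemistry is
deletion-heavy).  Profiling a handful of reference/read pairs recovers the
per-type frequencies and turns them into the weights, error budget tau and
frameshift allowance the clustering metric needs.

An insertion+deletion pair can occasionally mimic a substitution, and the
two cannot be separated from the strings alone, so the caller supplies two
likelihood hints using the ``less`` / ``more`` / ``equal`` vocabulary:
whether a substitution is less/more/equally likely than an indel pair, and
whether insertions are less/more/equally frequent than deletions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .distance import COLUMN
from .inference import _infer_one
from .params import WeightScheme, frameshift_positions

_HINTS = ("less", "more", "equal")


@dataclass(frozen=True)
class ErrorProfile:
    """Aggregated error counts with derived parameter suggestions."""

    bases_analyzed: int
    n_ins: int
    n_del: int
    n_sub: int

    @property
    def n_errors(self) -> int:
        return self.n_ins + self.n_del + self.n_sub

    @property
    def error_rate(self) -> float:
        """Percentage of analysed bases carrying an error."""
        if self.bases_analyzed == 0:
            return 0.0
        return 100.0 * self.n_errors / self.bases_analyzed

    def suggested_tau(self, length: int) -> int:
        """Expected error count for a sequence of ``length`` bases, rounded
        up — errors occur as whole numbers."""
        return max(int(math.ceil(self.error_rate / 100.0 * length)), 1)

    @property
    def suggested_weights(self) -> WeightScheme:
        return suggest_weights(self.n_ins, self.n_del, self.n_sub)


def suggest_weights(n_ins: int, n_del: int, n_sub: int) -> WeightScheme:
    """Map error-type frequencies to small integer weights.

    More frequent means cheaper: the majority indel type costs 1 and the
    minority 2, unless their counts are within 20 % of each other, in which
    case both cost 1.  Substitutions, unless they dominate, cost one more
    than an insertion and deletion combined, so that an indel pair is always
    preferred over a substitution where the profile says so.
    """
    hi, lo = max(n_ins, n_del), min(n_ins, n_del)
    if hi == 0 or lo / hi >= 0.8:
        w_ins = w_del = 1.0
    elif n_ins >= n_del:
        w_ins, w_del = 1.0, 2.0
    else:
        w_ins, w_del = 2.0, 1.0
    if n_sub > max(n_ins, n_del):
        w_sub = 1.0
    else:
        w_sub = w_ins + w_del + 1.0
    return WeightScheme(w_ins, w_del, w_sub)


def _hint_weights(sub_vs_indel_pair: str, ins_vs_del: str) -> WeightScheme:
    """Provisional weights that make the inference respect the hints."""
    if sub_vs_indel_pair not in _HINTS or ins_vs_del not in _HINTS:
        raise ValueError(f"hints must be one of {_HINTS}")
    if ins_vs_del == "more":
        wi, wd = 1.0, 2.0
    elif ins_vs_del == "less":
        wi, wd = 2.0, 1.0
    else:
        wi, wd = 1.0, 1.0
    if sub_vs_indel_pair == "less":
        ws = wi + wd + 1.0  # prefer the indel-pair reading
    elif sub_vs_indel_pair == "more":
        ws = min(wi, wd)  # prefer the substitution reading
    else:
        ws = wi + wd
    return WeightScheme(wi, wd, ws)


def profile_pair(
    reference: str,
    experimental: str,
    start_offset: int = 0,
    *,
    sub_vs_indel_pair: str = "less",
    ins_vs_del: str = "equal",
    frameshift: int | None = None,
) -> ErrorProfile:
    """Count errors between a reference and an experimental string.

    The strings must share a common beginning once ``start_offset`` is
    applied to the experimental string (determine the offset visually or by
    pairwise alignment when they do not).  The longer string is trimmed to
    the shorter's length; the trailing length mismatch is recovered through
    the border displacement of the inference, with the frameshift allowance
    defaulting to 15 % of the compared length.
    """
    reference = reference.upper()
    experimental = experimental.upper()[start_offset:]
    if not reference or not experimental:
        raise ValueError("reference and experimental strings must be non-empty")
    if reference[0] != experimental[0]:
        raise ValueError(
            "the strings do not share a common beginning; supply start_offset "
            "with the position of the reference start within the experimental read"
        )
    n = min(len(reference), len(experimental))
    ref, exp = reference[:n], experimental[:n]
    if frameshift is None:
        frameshift = frameshift_positions(n)
    cost, comp, s, (border, d) = _infer_one(
        ref, exp, _hint_weights(sub_vs_indel_pair, ins_vs_del), frameshift
    )
    # an insertion surplus pushes the reference tail past the compared
    # window: those d reference bases were never observed, so they do not
    # count as analysed
    covered = n - d if border == COLUMN else n
    return ErrorProfile(covered, comp.n_ins, comp.n_del, comp.n_sub)


def aggregate_profiles(profiles: list[ErrorProfile]) -> ErrorProfile:
    """Pool counts and bases across profiles; rate and suggestions follow."""
    if not profiles:
        raise ValueError("cannot aggregate an empty list of profiles")
    return ErrorProfile(
        sum(p.bases_analyzed for p in profiles),
        sum(p.n_ins for p in profiles),
        sum(p.n_del for p in profiles),
        sum(p.n_sub for p in profiles),
    )
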