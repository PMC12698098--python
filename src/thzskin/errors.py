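"""Exception hierarchy.

All package errors derive from :class:`ThzSkinError` so callers can catch one
type; each also derives from the closest builtin (ValueError / RuntimeError)
so untyped call sites behave sensibly.
"""
from __future__ import annotations


class ThzSkinError(Exception):
    """Base class for all thzskin errors."""


class GridMismatchError(ThzSkinError, ValueError):
    """Two objects that must share a frequency or time grid do not."""


class InvalidMaterialError(ThzSkinError, ValueError):
    """A dielectric model is unphysical (e.g. no terms and non-positive eps_inf)."""


class DomainError(ThzSkinError, ValueError):
    """An argument lies outside its physical domain."""


class ConfigurationError(ThzSkinError, ValueError):
    """A configuration object failed validation; the message names the field."""


class StackUsageError(ThzSkinError, RuntimeError):
    """An operation was applied to a layer/stack it is not defined for."""


class UndefinedCorrelationError(ThzSkinError, ValueError):
    """Pearson correlation requested with fewer than 3 samples."""


class EmptyInputError(ThzSkinError, ValueError):
    """An input file or directory contained no usable records."""


class NoConsensusError(ThzSkinError, RuntimeError):
    """Layer-count selection found no L acceptable at every ridge height.

    Carries the per-ridge-height acceptable sets for diagnosis.
    """

    def __init__(self, per_d_sets: dict[float, set[int]]):
        self.per_d_sets = dict(per_d_sets)
        detail = "; ".join(f"d={d} um -> {sorted(s)}" for d, s in self.per_d_sets.items())
        super().__init__(f"no layer count is acceptable at every ridge height ({detail})")
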