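"""Optional numba acceleration.

Rate-law functions are written as plain scalar Python; when numba is
importable they are compiled in nopython mode so the assembled ODE
right-hand side (which calls them) runs at native speed.  The same
function objects are what the unit tests exercise, so there is a single
source of truth for every flux expression.
"""

from __future__ import annotations

try:  # pragma: no cover - exercised implicitly by every import
    from numba import njit as _njit

    def njit(fn):
        return _njit(cache=True, fastmath=False)(fn)

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    def njit(fn):
        return fn

    HAVE_NUMBA = False
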