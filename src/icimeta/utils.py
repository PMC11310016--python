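"""Small shared numerics: monotone projection and deterministic seeding."""

from __future__ import annotations

import zlib

import numpy as np
from sklearn.isotonic import IsotonicRegression

__all__ = ["pav_nonincreasing", "substream_seed"]


def pav_nonincreasing(values: np.ndarray) -> np.ndarray:
    """Project a sequence onto the non-increasing cone (least squares).

    Pool-adjacent-violators via scikit-learn's isotonic regression with a
    decreasing constraint; used to restore monotonicity of digitized or
    jittered survival coordinates.
    """
    values = np.asarray(values, dtype=float)
    if len(values) <= 1:
        return values.copy()
    iso = IsotonicRegression(increasing=False)
    return iso.fit_transform(np.arange(len(values)), values)


def substream_seed(seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed (< 2**31) from a global seed.

    Keyed by the stage name so rerunning one pipeline stage never perturbs
    the random stream of another.
    """
    h = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    return int(np.random.SeedSequence([seed, h]).generate_state(1)[0] % (2**31))
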