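import numpy as np
import pytest

from actinf.fixtures import GlyphSpec, make_glyph_hypotheses


@pytest.fixture(scope="session")
def glyphs():
    """One shared glyph hypothesis set + matched noiseless scenes."""
    return make_glyph_hypotheses(GlyphSpec(seed=0))


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    p = np.clip(np.asarray(p, float), 1e-300, None)
    q = np.clip(np.asarray(q, float), 1e-300, None)
    return float(np.sum(p * np.log(p / q)))
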