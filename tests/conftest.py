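import numpy as np
import pytest

from cdszipf.rankfreq import assign_ranks, build_table
from cdszipf.synthetic import SyntheticSpec, sample_zm

CHAT_TEXT = """\
@UTF8
@Begin
@Languages:\teng
@Participants:\tMOT Mother, CHI Target_Child, INV Investigator
@ID:\teng|testcorp|MOT|32;00.|female|||Mother||
@ID:\teng|testcorp|CHI|1;0.|female|||Target_Child||
@ID:\teng|testcorp|INV|27;00.|male|||Investigator||
*MOT:\tthe doggy .
%mor:\tdet|the n|doggy .
*CHI:\tdoggy .
*INV:\twhere is the bunny ?
%mor:\tadv:wh|where v|is det|the n|bunny ?
*MOT:\t&=laughs xxx doggy [= the toy] !
@End
"""

HEADERS_ONLY = """\
@UTF8
@Begin
@Languages:\teng
@ID:\teng|testcorp|CHI|2;3.|female|||Target_Child||
@End
"""


@pytest.fixture
def chat_text():
    return CHAT_TEXT


@pytest.fixture
def headers_only():
    return HEADERS_ONLY


@pytest.fixture(scope="session")
def small_zm_ranked():
    """Ranked distribution from a modest Zipf-Mandelbrot stream (fast fits)."""
    spec = SyntheticSpec(alpha=1.4, beta=5.0, vocab_size=1_000, n_tokens=50_000, seed=11)
    tokens = sample_zm(spec)
    return spec, assign_ranks(build_table(tokens), tie_seed=0)


def grid_argmax(counts, alphas, betas):
    """Exhaustive grid-search oracle for the ZM multinomial likelihood."""
    counts = np.asarray(counts, dtype=float)
    r = np.arange(1, counts.size + 1, dtype=float)
    best = (-np.inf, None, None)
    for a in alphas:
        logw = -a * np.log(r[None, :] + np.asarray(betas)[:, None])
        logp = logw - np.log(np.exp(logw).sum(axis=1, keepdims=True))
        lls = logp @ counts
        i = int(np.argmax(lls))
        if lls[i] > best[0]:
            best = (float(lls[i]), float(a), float(betas[i]))
    return best
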