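"""Shared fixtures and the independent brute-force junction oracle."""

from __future__ import annotations

import numpy as np
import pytest

import uindel as u


# --------------------------------------------------------------------------
# independent oracle: direct definition scan, written separately from the
# package implementation (list-based max/min scans, no early-exit iterators)

def oracle_classify_and_call(u_vec, pre, can, es_lo):
    """Return (class name, jss, jes) straight from the definitions.

    Fully edited: matches the canonical U counts everywhere; pre-edited:
    matches the pre-edited counts; otherwise partial, with jss the
    3'-most ES disagreeing with the canonical sequence and jes the
    5'-most ES disagreeing with the pre-edited sequence.
    """
    u_vec, pre, can = list(u_vec), list(pre), list(can)
    if u_vec == can:
        return "FULLY_EDITED", None, None
    if u_vec == pre:
        return "PRE_EDITED", None, None
    jss = min(es_lo + i for i in range(len(u_vec)) if u_vec[i] != can[i])
    jes = max(es_lo + i for i in range(len(u_vec)) if u_vec[i] != pre[i])
    return "PARTIALLY_EDITED", jss, jes


@pytest.fixture(scope="session")
def oracle():
    return oracle_classify_and_call


# --------------------------------------------------------------------------
# scaffolds

@pytest.fixture(scope="session")
def toy():
    """4-ES toy scaffold: backbone GACGA, pre_u (1,0,2,0), can_u (0,3,2,1)."""
    s = u.build_scaffold("GATTCGTA", "GTATTCTTTGA", "toy")
    return s, u.full_window(s)


@pytest.fixture(scope="session")
def synthetic():
    """150-ES synthetic reference pair with its 16-nt flank primers."""
    pre, edt = u.synthetic_reference_pair(n_es=150)
    s = u.build_scaffold(pre, edt, "synthetic")
    w = u.restrict_to_amplicon(s, pre[:16], pre[-16:])
    return s, w


def random_scaffold(rng: np.random.Generator, n_res: int | None = None,
                    max_u: int = 10) -> u.EditingScaffold:
    """Random editing pair: A/C/G backbone with independent U counts."""
    if n_res is None:
        n_res = int(rng.integers(3, 40))
    backbone = "".join(rng.choice(list("ACG"), size=n_res))
    n_es = n_res - 1
    pre_u = tuple(int(x) for x in rng.integers(0, max_u + 1, size=n_es))
    can_u = tuple(int(x) for x in rng.integers(0, max_u + 1, size=n_es))
    return u.EditingScaffold("rand", backbone, pre_u, can_u)


@pytest.fixture()
def make_profile():
    """Construct a minimal SampleProfile from a JES histogram."""
    import pandas as pd

    def _make(jes_hist, *, sample_id="s", condition="c", replicate=1,
              es_lo=1, es_hi=200):
        return u.SampleProfile(
            sample_id=sample_id, condition=condition, replicate=replicate,
            es_lo=es_lo, es_hi=es_hi, n_reads=0, n_excluded=0,
            exclusion_counts={}, class_counts={}, jes_hist=dict(jes_hist),
            seq_table=pd.DataFrame(
                columns=["u_vector", "read_class", "jss", "jes", "count_norm"]
            ),
        )

    return _make
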