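import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cismr import simulate as sim
from cismr.summary_io import LDMatrix


def make_summary(
    pos, beta, se, eaf=0.3, ea="A", oa="G", chrom="1", pvalue=None, n=10000.0
):
    """Small canonical summary frame from parallel lists."""
    k = len(pos)
    from scipy import stats

    def bc(x):
        x = np.asarray(x, dtype=float)
        return np.broadcast_to(x, (k,)).copy()

    beta = bc(beta)
    se = bc(se)
    if pvalue is None:
        pvalue = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": list(pos),
            "rsid": [f"rs{p}" for p in pos],
            "ea": ea if isinstance(ea, list) else [ea] * k,
            "oa": oa if isinstance(oa, list) else [oa] * k,
            "eaf": bc(eaf),
            "beta": beta,
            "se": se,
            "pvalue": bc(pvalue),
            "n": bc(n),
        }
    )


def ld_from_r(pos, r, chrom="1"):
    keys = [f"{chrom}:{p}" for p in pos]
    return LDMatrix(keys, np.asarray(r, dtype=float), "test")


@pytest.fixture(scope="session")
def small_panel():
    spec = sim.ScenarioSpec(
        n_variants=40, n_haplotypes=600, ld_decay=0.6, seed=42
    )
    return sim.simulate_panel(spec), spec
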