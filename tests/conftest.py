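import numpy as np
import pytest
from scipy.stats import norm

from mrpipe.instrumenting import HarmonizedSet
from mrpipe.summary_data import AssociationRecord, GwasTable


def record(snp="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=None, n=100_000,
           eaf=0.3, **kw):
    if pval is None:
        if se > 0:
            pval = float(max(2.0 * norm.sf(abs(beta / se)), 1e-300))
        else:
            pval = 0.5
    return AssociationRecord(snp_id=snp, effect_allele=ea, other_allele=oa,
                             beta=beta, se=se, pval=pval, n=n, eaf=eaf, **kw)


def make_table(rows, name="trait", **meta):
    """Build a GwasTable from a list of record-kwarg dicts."""
    t = GwasTable(trait_name=name, **meta)
    for r in rows:
        t.add(record(**r))
    return t


def make_harmonized(bx, by, sy, sx=None, binary=False):
    """Build a HarmonizedSet directly from effect arrays (already aligned)."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    j = len(bx)
    ids = [f"rs{i + 1}" for i in range(j)]
    pvals = np.maximum(2.0 * norm.sf(np.abs(bx / sx)), 1e-300)
    return HarmonizedSet(
        snp_ids=ids, beta_exp=bx, se_exp=sx, beta_out=by, se_out=sy,
        eaf_exp=np.full(j, 0.3), eaf_out=np.full(j, 0.3), pval_exp=pvals,
        effect_allele=["A"] * j, other_allele=["G"] * j,
        actions={s: "unchanged" for s in ids},
        exposure_name="exp", outcome_name="out", outcome_binary=binary,
        n_exp=100_000, n_out=100_000,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
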