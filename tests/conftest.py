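import itertools

import numpy as np
import pytest

from kinact import PhosphoSite


def make_site(protein, position, residue="S", folds=None, regulated=(), source=("A",)):
    return PhosphoSite(
        protein=protein,
        position=position,
        residue=residue,
        condition_fold=dict(folds or {}),
        regulated_in=set(regulated),
        source=set(source),
    )


def collection(*sites):
    return {s.key: s for s in sites}


# ---------------------------------------------------------------------------
# Independent brute-force oracles for the KS machinery. These deliberately
# use the naive O(n*m) definitions, sharing no code with the implementation.
# ---------------------------------------------------------------------------

def brute_force_ks(x, y):
    """sup-norm ECDF distances evaluated by direct counting."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    d_plus = d_minus = 0.0
    for t in np.concatenate([x, y]):
        f_x = np.mean(x <= t)
        f_y = np.mean(y <= t)
        d_plus = max(d_plus, f_y - f_x)
        d_minus = max(d_minus, f_x - f_y)
    return max(d_plus, d_minus), d_plus, d_minus


def brute_force_exact_p(x, y, side="two"):
    """Exact permutation p by full enumeration of group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n = len(x)

    def stat(xs, ys):
        d, dp, dm = brute_force_ks(xs, ys)
        return {"two": d, "up": dp, "down": dm}[side]

    observed = stat(x, y)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(combo)] = True
        hits += stat(pooled[mask], pooled[~mask]) >= observed - 1e-12
        total += 1
    return hits / total


@pytest.fixture
def rng():
    return np.random.default_rng(20140410)
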