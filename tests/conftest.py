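import numpy as np
import pytest

from anovatab import GroupSummary, ResponseSummary


def random_summary(rng, k=None, balanced=True, n_choices=(6, 8, 10),
                   variable="y") -> ResponseSummary:
    """A random per-group summary drawn from a one-way normal model.

    Group sizes come from a small grid so the studentized-range quantile
    cache stays effective across many generated rows.
    """
    if k is None:
        k = int(rng.integers(3, 6))
    if balanced:
        ns = [int(rng.choice(n_choices))] * k
    else:
        ns = [int(rng.choice(n_choices)) for _ in range(k)]
    groups = []
    for i in range(k):
        ys = rng.normal(rng.uniform(-1, 1), 1.0, size=ns[i])
        groups.append(GroupSummary(
            label=f"g{i + 1}", n=ns[i], mean=float(np.mean(ys)),
            dispersion=float(np.std(ys, ddof=1)), dispersion_kind="sd"))
    return ResponseSummary(variable=variable, groups=tuple(groups))


@pytest.fixture
def rng():
    return np.random.default_rng(20140827)
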