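import numpy as np
import pandas as pd
import pytest

import n2onet as nn


@pytest.fixture
def toy_table() -> nn.CountTable:
    """5 taxa x 4 samples with hand-computable relative abundances."""
    counts = pd.DataFrame(
        {
            "s1": [50, 30, 15, 5, 0],
            "s2": [40, 35, 20, 5, 0],
            "s3": [45, 35, 15, 4, 1],
            "s4": [55, 25, 15, 5, 0],
        },
        index=["t1", "t2", "t3", "t4", "t5"],
    )
    metadata = pd.DataFrame(
        {"treatment": ["a", "a", "b", "b"], "replicate": [1, 2, 1, 2]},
        index=counts.columns,
    )
    return nn.CountTable(counts, metadata)


@pytest.fixture(scope="session")
def power_runs():
    """Fifty seeded power-preset analyses, shared across recovery tests.

    Each entry holds the planted truth, the inferred partition, the
    module-abundance regressions, and the per-sample z-scored matrix.
    """
    runs = []
    for seed in range(50):
        cfg = nn.power_config(seed=seed)
        table, n2o, env, truth = nn.generate_community(cfg)
        filt = nn.filter_low_abundance(table)
        norm = nn.normalize(filt)
        corr = nn.spearman_matrix(norm)
        net = nn.threshold_network(corr)
        part = nn.detect_modules(net, seed=seed)
        z, _ = nn.zscore(norm.rel_abund)
        regs = nn.module_abundance_regression(z, part, n2o)
        runs.append(
            {
                "truth": truth,
                "part": part,
                "regs": regs,
                "z": z,
                "n2o": n2o,
                "net": net,
                "seed": seed,
            }
        )
    return runs


def match_modules(part, truth, min_size: int = 3) -> dict[int, int]:
    """Map planted module -> detected module by majority overlap."""
    mapping = {}
    planted = {}
    for taxon, m in truth.true_partition.items():
        planted.setdefault(m, set()).add(taxon)
    for m, members in planted.items():
        if m == 0:
            continue
        best, best_overlap = None, 0
        for d in part.modules:
            overlap = len(members & set(part.members(d)))
            if overlap > best_overlap:
                best, best_overlap = d, overlap
        mapping[m] = best
    return mapping
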