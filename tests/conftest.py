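import numpy as np
import pandas as pd
import pytest

from entrapbench import DiscoveryTable, ProteinRecord


@pytest.fixture(scope="session")
def synthetic_proteome():
    """200 tryptic-looking proteins: random peptides terminated by K/R."""
    rng = np.random.default_rng(42)
    aas = np.array(list("ACDEFGHILMNPQSTVWY"))
    proteins = []
    for i in range(200):
        n_pep = rng.integers(4, 10)
        seq = "".join(
            "".join(rng.choice(aas, rng.integers(6, 16)))
            + ("K" if rng.random() < 0.5 else "R")
            for _ in range(n_pep))
        proteins.append(ProteinRecord(f"SYN{i:04d}", f"SYN{i:04d} synthetic",
                                      seq))
    return proteins


def make_table(rows):
    """Build a DiscoveryTable from (id, label, score, q, pair_key) tuples."""
    return DiscoveryTable(pd.DataFrame(
        rows, columns=["id", "label", "score", "q_value", "pair_key"]))


@pytest.fixture
def random_table_factory():
    """Random paired discovery tables for oracle-equivalence sweeps."""

    def build(rng, n_pairs=None):
        n = int(n_pairs if n_pairs is not None else rng.integers(5, 500))
        t_scores = rng.normal(1.0, 2.0, n)
        e_scores = rng.normal(0.0, 2.0, n)
        # duplicate some scores to exercise tie handling
        dup = rng.random(n) < 0.1
        e_scores[dup] = t_scores[dup]
        rows = []
        for i in range(n):
            if rng.random() < 0.9:
                rows.append((f"T{i}", "original", t_scores[i],
                             rng.random(), ""))
            if rng.random() < 0.9:
                rows.append((f"E{i}", "entrapment", e_scores[i],
                             rng.random(), f"T{i}"))
        pairs = {f"T{i}": [f"E{i}"] for i in range(n)}
        return make_table(rows), pairs

    return build
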