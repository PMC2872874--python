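import numpy as np
import pandas as pd
import pytest

from lenrich.io_annotation import CategoryMap, GeneTable


@pytest.fixture
def small_table() -> GeneTable:
    frame = pd.DataFrame(
        {
            "length_bp": [500.0, 1500.0, 3000.0],
            "count_1": [10, 40, 90],
            "count_2": [12, 35, 100],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    return GeneTable(frame, lib_sizes=(140, 147))


@pytest.fixture
def small_map() -> CategoryMap:
    return CategoryMap(
        {
            "A": frozenset({"g1", "g2"}),
            "B": frozenset({"g2", "g3"}),
        }
    )


@pytest.fixture
def counts_file(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "gene_id\tcount_cond1\tcount_cond2\n"
        "g1\t10\t12\n"
        "g2\t40\t35\n"
        "g3\t90\t100\n"
    )
    return path


@pytest.fixture
def lengths_file(tmp_path):
    path = tmp_path / "lengths.tsv"
    path.write_text("gene_id\tlength_bp\ng1\t500\ng2\t1500\ng3\t3000\n")
    return path


@pytest.fixture
def categories_file(tmp_path):
    path = tmp_path / "categories.tsv"
    path.write_text("g1\tA\ng2\tA\ng2\tB\ng3\tB\n")
    return path


def wallenius_enumerate(N: int, K: int, n: int, omega: float) -> np.ndarray:
    """Exact pmf of the biased-urn draw count by exhaustive sequential-draw DP.

    Independent oracle: forward dynamic programme over (drawn-in, drawn-out)
    states with per-draw probability proportional to remaining weight.
    """
    probs = {(0, 0): 1.0}
    for _ in range(n):
        nxt: dict[tuple[int, int], float] = {}
        for (a, b), p in probs.items():
            k_rem = K - a
            o_rem = (N - K) - b
            tot = omega * k_rem + o_rem
            if k_rem > 0:
                nxt[(a + 1, b)] = nxt.get((a + 1, b), 0.0) + p * omega * k_rem / tot
            if o_rem > 0:
                nxt[(a, b + 1)] = nxt.get((a, b + 1), 0.0) + p * o_rem / tot
        probs = nxt
    pmf = np.zeros(min(K, n) + 1)
    for (a, _b), p in probs.items():
        pmf[a] += p
    return pmf
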