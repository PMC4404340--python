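import numpy as np
import pytest

from mitopop.seqio import Alignment


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment.from_records(
        [
            ("s1", "ACGTACGTAC"),
            ("s2", "ACGTACGTAC"),
            ("s3", "ACGTACGTAT"),
            ("s4", "ACGAACGTAT"),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240117)


def random_alignment(rng, n=8, L=30, n_var=6) -> Alignment:
    """Random alignment with ~n_var variable binary-state columns."""
    bases = np.array(list("ACGT"))
    root = rng.choice(bases, size=L)
    mat = np.tile(root, (n, 1))
    var_sites = rng.choice(L, size=n_var, replace=False)
    for s in var_sites:
        alt = rng.choice([b for b in "ACGT" if b != root[s]])
        carriers = rng.choice(n, size=rng.integers(1, n), replace=False)
        mat[carriers, s] = alt
    return Alignment.from_records(
        (f"s{i + 1}", "".join(row)) for i, row in enumerate(mat)
    )
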