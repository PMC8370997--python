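import logging

import numpy as np
import pandas as pd
import pytest

from paradapt.genotypes import GenotypeMatrix

logging.getLogger("paradapt").setLevel(logging.ERROR)


def make_gm(dosage, pops, ploidy=4, positions=None, chrom="chr1", depth=None):
    """GenotypeMatrix from a dense dosage array and per-row population labels."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n_ind, n_sites = dosage.shape
    individuals = [f"i{k}" for k in range(n_ind)]
    pop_of = {f"i{k}": pops[k] for k in range(n_ind)}
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(
        individuals=individuals,
        pop_of=pop_of,
        ploidy=ploidy,
        sites=sites,
        dosage=dosage,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
    )


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """One tiny simulated file bundle shared across the session."""
    from paradapt.simulate import emit_fixture

    outdir = tmp_path_factory.mktemp("tiny_fixture")
    manifest = emit_fixture(size="tiny", outdir=str(outdir), seed=7)
    return manifest


@pytest.fixture(scope="session")
def quartet_F0():
    """A split-model coancestry matrix for an (S1, N1, S2, N2) quartet."""
    return np.array(
        [
            [0.033, 0.0083, 0.0, 0.0],
            [0.0083, 0.033, 0.0, 0.0],
            [0.0, 0.0, 0.033, 0.0083],
            [0.0, 0.0, 0.0083, 0.033],
        ]
    )
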