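import numpy as np
import pandas as pd
import pytest

from vpaglio.io import CountMatrix, GeneAnnotation, SampleMeta
from vpaglio.simulate import gen_annotation, gen_counts


@pytest.fixture(scope="session")
def small_annotation() -> GeneAnnotation:
    return gen_annotation(400, n_chroms=3, seed=101)


@pytest.fixture(scope="session")
def poisson_dataset(small_annotation):
    """14-line Poisson-mode dataset with fully supported planted genes."""
    cm, truth = gen_counts(
        small_annotation, seed=202, noise="poisson", support_per_lineage=7, frac_up=0.05,
        family_size=20, n_family_planted=8,
    )
    return cm, truth


@pytest.fixture(scope="session")
def lineages14():
    from vpaglio.simulate import ADHERENT_LINES, STEM_LINES

    return {**{l: "adherent" for l in ADHERENT_LINES}, **{l: "stem" for l in STEM_LINES}}


def tiny_count_matrix(counts: np.ndarray, gene_ids, lines_conditions) -> CountMatrix:
    """Helper: build a CountMatrix from an array and (line, lineage, cond) tuples."""
    samples = [
        SampleMeta(
            sample_id=f"{line}_{cond}",
            cell_line=line,
            lineage=lineage,
            condition=cond,
            library_size=1_000_000,
        )
        for line, lineage, cond in lines_conditions
    ]
    df = pd.DataFrame(counts, index=gene_ids, columns=[s.sample_id for s in samples])
    return CountMatrix(counts=df, samples=samples)
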