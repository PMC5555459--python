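import numpy as np
import pandas as pd
import pytest

from nucmorph import qtlmap, synthgen


@pytest.fixture(scope="session")
def five_chrom_map():
    """5 chromosomes x 100 cM, markers every 5 cM (105 markers)."""
    return synthgen.make_genetic_map(5, [100.0] * 5, 5.0)


@pytest.fixture(scope="session")
def ril_population(five_chrom_map):
    return synthgen.simulate_ril_genotypes(five_chrom_map, 46, seed=11)


@pytest.fixture(scope="session")
def prob_grid(five_chrom_map, ril_population):
    return qtlmap.genotype_probs(five_chrom_map, ril_population, 1.0)


@pytest.fixture()
def rendered_field():
    """One 512x512 field of 4 nuclei with known ground truth, low noise."""
    truths = synthgen.random_nucleus_field(4, (512, 512), seed=3, noise_sd=2.0)
    img, nmask, cmask = synthgen.render_nucleus_image(truths, (512, 512), seed=4)
    return truths, img, nmask, cmask


@pytest.fixture()
def simple_trait_table():
    """3 lines x 4 nuclei from 2 plants each, hand-set values."""
    rows = []
    for line, base in (("L1", 10.0), ("L2", 20.0), ("L3", 30.0)):
        for k, dv in enumerate((-1.0, -0.5, 0.5, 1.0)):
            rows.append({"line_id": line, "plant_id": f"P{k % 2 + 1}",
                         "nucleus_id": k + 1, "trait": base + dv})
    return pd.DataFrame(rows)
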