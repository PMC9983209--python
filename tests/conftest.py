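import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

import eukbench as eb


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def small_panel():
    """Six organisms incl. one strain pair, default (wide) family divergence."""
    cfg = eb.PanelConfig(
        n_organisms=6,
        genes_per_organism=20,
        gene_length=(306, 900),
        n_strain_pairs=1,
        seed=7,
    )
    return eb.generate_panel(cfg)


@pytest.fixture(scope="session")
def tight_panel():
    """Panel with within-family pairwise divergence ~10% (5% per member),
    the regime where orthogroup inference should recover truth exactly."""
    cfg = eb.PanelConfig(
        n_organisms=4,
        genes_per_organism=15,
        gene_length=(306, 600),
        within_family_sub_rate=0.05,
        n_strain_pairs=0,
        seed=11,
    )
    return eb.generate_panel(cfg)


@pytest.fixture(scope="session")
def designer(small_panel):
    """Template-2 community over the small panel plus its designer set."""
    spec = eb.make_template(
        2,
        small_panel.organism_ids(),
        seed=3,
        strain_pairs=small_panel.strain_pairs,
        budget=40,
    )
    records, manifest = eb.select_contigs(
        spec, small_panel, small_panel.truth_orthogroups, seed=3
    )
    return spec, records, manifest
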