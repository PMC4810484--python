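import numpy as np
import pytest

from steromine.align import default_scheme
from steromine.simulate import CommunityConfig, generate_reference_panel


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def panel():
    return generate_reference_panel(seed=1)


@pytest.fixture(scope="session")
def small_community():
    """A quick community shared by unit tests (small decoy load)."""
    from steromine.simulate import generate_community

    cfg = CommunityConfig(
        n_genomes=8, degrader_fraction=0.5, n_decoys_per_genome=30, seed=11
    )
    return generate_community(cfg)


@pytest.fixture(scope="session")
def study_run():
    """The study-condition end-to-end run: 20 genomes, half of them planted
    degraders at 50-70% identity, 500 decoys per genome."""
    from steromine.pipeline import PipelineConfig, run_pipeline

    cc = CommunityConfig(
        n_genomes=20, degrader_fraction=0.5, n_decoys_per_genome=500, seed=42
    )
    pc = PipelineConfig(seed=42, phylo_bootstrap=100)
    report = run_pipeline(pc, community=cc)
    return report


@pytest.fixture(scope="session")
def congruence_runs():
    """Two single-pathway communities on one species tree: pure vertical
    descent, and the same with one long-range horizontal transfer."""
    from steromine.pipeline import PipelineConfig, run_pipeline
    from steromine.simulate import balanced_species_tree

    ids = [f"G{i + 1:02d}" for i in range(10)]
    tree = balanced_species_tree(ids)
    side_a, side_b = tree.children
    donor = min(t.name for t in side_a.tips())
    recipient = min(t.name for t in side_b.tips())
    base = dict(
        n_genomes=10,
        degrader_fraction=1.0,
        n_decoys_per_genome=40,
        pathway_templates=["cholate"],
        seed=33,
        species_tree=tree,
    )
    pc = PipelineConfig(seed=33, phylo_bootstrap=100)
    vertical = run_pipeline(pc, community=CommunityConfig(**base))
    hgt = run_pipeline(
        pc, community=CommunityConfig(hgt_events=[(donor, recipient, "cholate")], **base)
    )
    return vertical, hgt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
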