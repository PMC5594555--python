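"""Shared fixtures: one small synthetic genome, mined and annotated once.

The 20-gene family at 10% paralog divergence is the workhorse fixture;
it is generated (not stored) and reused across modules because mining is
the slow step.
"""

from __future__ import annotations

import pytest

from famscan.mine import MiningParams, iterative_mine
from famscan.models import assemble_gene_models, classify_architecture
from famscan.motifs import classify_receptor_signaling
from famscan.pipeline import EXPECTED_EXON_LENGTHS
from famscan.simulate import FamilySpec, generate_truth

SMALL_SPEC = FamilySpec(n_genes=20, contig_count=3, seed=7)


@pytest.fixture(scope="session")
def small_truth():
    return generate_truth(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_calls(small_truth):
    return iterative_mine(
        small_truth.contigs,
        small_truth.ancestors.seed_queries,
        EXPECTED_EXON_LENGTHS,
        MiningParams(),
    )


@pytest.fixture(scope="session")
def small_models(small_truth, small_calls):
    models = assemble_gene_models(small_calls, species="syn")
    for m in models:
        classify_architecture(m, small_truth.ancestors.igc_references)
        rc = classify_receptor_signaling(
            m,
            small_truth.ancestors.tm_references,
            small_truth.contigs[m.contig_id],
        )
        m.signaling = rc.signaling
    return models


def truth_by_n_exon(truth):
    """Map (contig, N-exon interval) -> planted gene for model/truth joins."""
    return {(g.contig_id, g.n_exon.start, g.n_exon.end): g for g in truth.genes}


SIGNALING_TO_ARCH = {
    "inhibitory": "CEACAM-ITIM",
    "inhibitory-ITSM": "CEACAM-ITSM",
    "activating": "CEACAM-ITAM",
    "nonfunctional": "CEACAM-nonfunctional",
}


def predicted_architecture(model) -> str:
    """Collapse architecture + signaling into the planted truth vocabulary."""
    if model.architecture.startswith("PSG"):
        return model.architecture
    return SIGNALING_TO_ARCH.get(model.signaling, model.architecture)
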