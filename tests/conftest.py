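import numpy as np
import pytest

import syncliptic as sc
from syncliptic.io import GenomeAnnotation, SequenceStore, Transcript

# the canonical fixture seed used throughout the suite
FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def toy_annotation() -> GenomeAnnotation:
    """Hand-built annotation covering every feature class and precedence conflict.

    gA (+, coding): exons [1,201)+[301,501), CDS [101,401)
        -> 5'UTR [1,101), intron [201,301), 3'UTR [401,501)
    gB (-, coding): exons [1000,1200)+[1300,1500), CDS [1100,1400)
        -> 3'UTR [1000,1100), intron [1200,1300), 5'UTR [1400,1500)
    gC (+, non-coding single exon): [2000,2300)
    gE (+): t1 coding exons [3000,3200)+[3400,3600), CDS [3050,3450);
            t2 non-coding exons [3000,3100)+[3500,3600)
            -> positions that are UTR in t1 but exon/intron in t2
    gF (+, non-coding single exon): [3550,3800), overlapping gE
    """
    ann = GenomeAnnotation()
    ann.add_transcript(
        "gA",
        Transcript(
            "gA.t1", "chr1", "+", [(1, 201), (301, 501)], [(101, 201), (301, 401)]
        ),
    )
    ann.add_transcript(
        "gB",
        Transcript(
            "gB.t1",
            "chr1",
            "-",
            [(1000, 1200), (1300, 1500)],
            [(1100, 1200), (1300, 1400)],
        ),
    )
    ann.add_transcript("gC", Transcript("gC.t1", "chr1", "+", [(2000, 2300)]))
    ann.add_transcript(
        "gE",
        Transcript(
            "gE.t1",
            "chr1",
            "+",
            [(3000, 3200), (3400, 3600)],
            [(3050, 3200), (3400, 3450)],
        ),
    )
    ann.add_transcript(
        "gE", Transcript("gE.t2", "chr1", "+", [(3000, 3100), (3500, 3600)])
    )
    ann.add_transcript("gF", Transcript("gF.t1", "chr1", "+", [(3550, 3800)]))
    return ann


@pytest.fixture(scope="session")
def toy_genome() -> SequenceStore:
    rng = np.random.default_rng(123)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return SequenceStore({"chr1": bytes(alphabet[rng.integers(0, 4, 6000)]).decode()})


@pytest.fixture(scope="session")
def clip_annotation():
    return sc.simulate_annotation(4000, seed=70)


@pytest.fixture(scope="session")
def clip_fixture(clip_annotation):
    """The default synthetic CLIP experiment: 20k peaks, 5% enriched."""
    ann, _ = clip_annotation
    return sc.simulate_clip_experiment(
        ann, 20000, frac_enriched=0.05, phi=0.1, seed=FIXTURE_SEED
    )


@pytest.fixture(scope="session")
def clip_null_fixture(clip_annotation):
    ann, _ = clip_annotation
    return sc.simulate_clip_experiment(
        ann, 20000, frac_enriched=0.0, phi=0.1, seed=FIXTURE_SEED
    )


def normalized_adjusted_profile(sim):
    """TMM effective library sizes -> M/A -> robust LOESS adjustment."""
    cm = sim.count_matrix()
    eff = sc.tmm_factors(cm).effective_lib_size
    prof = sc.make_ma_profile(
        cm.counts.index.to_numpy(),
        cm.counts["x"].to_numpy(),
        cm.counts["y"].to_numpy(),
        eff["x"],
        eff["y"],
        o=1.0,
    )
    return sc.adjust_m(prof, span=0.25, robust_iterations=4)


@pytest.fixture(scope="session")
def adjusted_profile(clip_fixture):
    return normalized_adjusted_profile(clip_fixture)


@pytest.fixture(scope="session")
def adjusted_null_profile(clip_null_fixture):
    return normalized_adjusted_profile(clip_null_fixture)


@pytest.fixture(scope="session")
def stability_fixture():
    return sc.simulate_stability_timecourse(
        2000, frac_stabilized=0.1, seed=FIXTURE_SEED
    )


@pytest.fixture(scope="session")
def stability_de(stability_fixture):
    """Per-time-point two-group NB test results on the stability fixture."""
    groups = ["wt"] * 6 + ["mut"] * 6
    return {
        t: sc.nb_de_two_group(cm, groups)
        for t, cm in stability_fixture.counts.items()
    }


def full_enrichment(sim, profile=None):
    """Normalization + dispersion + per-peak LRT, as the pipeline composes them."""
    prof = profile if profile is not None else normalized_adjusted_profile(sim)
    mask = sc.center_cloud_mask(prof)
    ox, oy = sc.peak_offsets(prof.lib_x, prof.lib_y, prof.fitted)
    disp = sc.estimate_common_dispersion(
        prof.x[mask], prof.y[mask], ox[mask], oy[mask]
    )
    table = sc.enrichment_table(prof, disp.phi)
    return prof, disp, table
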