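import numpy as np
import pytest

import crafdseq as cs


def make_track(values, strand="F", label="lib", normalized=False, genome_id="g"):
    return cs.CoverageTrack(
        genome_id=genome_id,
        strand=strand,
        values=np.asarray(values, dtype=float),
        label=label,
        normalized=normalized,
    )


@pytest.fixture
def step_track():
    """10 for positions 1-50, 20 for 51-120, 10 for 121-200."""
    v = np.concatenate([np.full(50, 10.0), np.full(70, 20.0), np.full(80, 10.0)])
    return make_track(v)


def random_count_track(rng, length, n_steps=3, background=20, strand="F"):
    """Integer-valued random track: Poisson background with a few planted
    multiplicative steps (integer-valued so float sums are exact)."""
    lam = np.full(length, float(background))
    for _ in range(n_steps):
        w = int(rng.integers(10, max(11, length // 4)))
        start = int(rng.integers(0, max(1, length - w)))
        lam[start : start + w] *= float(rng.uniform(1.2, 5.0))
    return make_track(rng.poisson(lam).astype(float), strand=strand)


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic experiment (seed 42), shared across tests."""
    cfg = cs.SimulationConfig(seed=42)
    fs = cs.simulate_annotation(cfg)
    libs = cs.simulate_libraries(cfg, fs)
    return cfg, fs, libs


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """Small synthetic experiment written to disk, with split per-library
    grp files, for pipeline and CLI tests."""
    root = tmp_path_factory.mktemp("sim")
    cfg = cs.SimulationConfig(seed=5, genome_length=30000, n_genes=25,
                              n_true_peaks=12, n_decoy_peaks=4)
    fs = cs.simulate_annotation(cfg)
    libs = cs.simulate_libraries(cfg, fs)
    cs.write_simulation(cfg, fs, libs, root)
    for i, rep in enumerate(libs.pulldown, start=1):
        for strand, tag in (("F", "fwd"), ("R", "rev")):
            cs.write_grp(cs.GrpFile.from_tracks([rep[strand]]),
                         root / f"rep{i}_{tag}.grp")
    for strand, tag in (("F", "fwd"), ("R", "rev")):
        cs.write_grp(cs.GrpFile.from_tracks([libs.control[strand]]),
                     root / f"ctrl_{tag}.grp")
    return root, cfg, fs, libs


def make_config(root, outdir, ranks=None):
    """Pipeline configuration over a sim_dir root."""
    return cs.PipelineConfig(
        pulldown=[
            cs.LibraryInput("pulldown_rep1", str(root / "rep1_fwd.grp"),
                            str(root / "rep1_rev.grp")),
            cs.LibraryInput("pulldown_rep2", str(root / "rep2_fwd.grp"),
                            str(root / "rep2_rev.grp")),
        ],
        control=cs.LibraryInput("control", str(root / "ctrl_fwd.grp"),
                                str(root / "ctrl_rev.grp")),
        gff=str(root / "genome.gff3"),
        ranks=ranks,
        outdir=str(outdir),
    )


@pytest.fixture(scope="session")
def default_sim_calls(default_sim):
    """Enrichment calls from the full in-memory pipeline on the default sim."""
    _, _, libs = default_sim

    def norm(tracks):
        total = tracks["F"].total() + tracks["R"].total()
        return {s: cs.normalize_to_library_size(t, total) for s, t in tracks.items()}

    reps = [norm(r) for r in libs.pulldown]
    ctrl = norm(libs.control)
    merged = {s: cs.merge_tracks([r[s] for r in reps], "mean") for s in ("F", "R")}
    peaks = cs.call_peaks_stranded(merged["F"], merged["R"])
    calls = []
    for s in ("F", "R"):
        strand_peaks = [p for p in peaks if p.strand == s]
        calls.extend(
            cs.classify_peaks(strand_peaks, [r[s] for r in reps], ctrl[s])
        )
    return peaks, calls
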