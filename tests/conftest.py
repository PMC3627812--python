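import numpy as np
import pandas as pd
import pytest

import predaseq as pq


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale study conditions used by the recovery suites."""
    return pq.SimulationSpec(
        genome_length=60_000, n_genes=50, n_srnas=4,
        library_size_ap=100_000, library_size_gp=100_000,
        tap_plus_depth=40_000, tap_minus_depth=30_000, seed=11,
    )


@pytest.fixture(scope="session")
def bundle(small_spec):
    """One simulated bundle shared by the recovery tests (read-only)."""
    genome, genes, truth = pq.generate_genome(small_spec)
    ap, gp = pq.simulate_alignments(genome, truth, small_spec)
    tap_plus, tap_minus = pq.simulate_5prime_tracks(truth, small_spec)
    return {"spec": small_spec, "genome": genome, "genes": genes, "truth": truth,
            "ap": ap, "gp": gp, "tap_plus": tap_plus, "tap_minus": tap_minus}


@pytest.fixture(scope="session")
def expression_table(bundle):
    return pq.build_table(bundle["ap"], bundle["gp"], bundle["genes"])


@pytest.fixture(scope="session")
def planted_promoters():
    """100 synthetic 50-base promoters, 66 carrying TTAAG-N16-CCGATA."""
    rng = np.random.default_rng(2013)
    bases = np.array(list("ACGT"))

    def rand(n):
        return "".join(bases[rng.integers(0, 4, n)])

    promoters = []
    for i in range(100):
        if i < 66:
            promoters.append(rand(16) + "TTAAG" + rand(16) + "CCGATA" + rand(7))
        else:
            promoters.append(rand(50))
    return promoters


@pytest.fixture(scope="session")
def consensus_motif():
    """A sharp two-box model built from the consensus words."""
    def pwm_from(word):
        idx = {b: i for i, b in enumerate("ACGT")}
        m = np.full((4, len(word)), 0.01)
        for j, b in enumerate(word):
            m[idx[b], j] = 0.97
        return m / m.sum(axis=0, keepdims=True)

    weights = np.array([0.05, 0.1, 0.7, 0.1, 0.05])
    return pq.TwoBoxMotif(pwm35=pwm_from("TTAAG"), pwm10=pwm_from("CCGATA"),
                          spacer_min=14, spacer_max=18,
                          spacer_weights=weights, score_threshold=5.0)


@pytest.fixture(scope="session")
def irregular_motif():
    """Tie-free motif (distinct Dirichlet columns) for argmax-oracle checks."""
    rng = np.random.default_rng(424)
    pwm35 = rng.dirichlet([2, 2, 2, 2], size=5).T
    pwm10 = rng.dirichlet([2, 2, 2, 2], size=6).T
    weights = rng.dirichlet([3, 3, 3, 3, 3])
    return pq.TwoBoxMotif(pwm35=pwm35, pwm10=pwm10, spacer_min=14,
                          spacer_max=18, spacer_weights=weights,
                          score_threshold=-1e9)


def make_track(entries, treatment="TAP_plus"):
    """FivePrimeTrack from [(position, strand, count), ...]."""
    df = pd.DataFrame(entries, columns=["position", "strand", "count"])
    return pq.FivePrimeTrack(counts=df, treatment=treatment)


def tss_match(calls: pd.DataFrame, truth_tss: pd.DataFrame, tol: int = 2):
    """(sensitivity, precision) of calls against planted TSSs, +/- tol nt."""
    truth_set = set(zip(truth_tss["position"], truth_tss["strand"]))
    call_set = set(zip(calls["position"], calls["strand"]))
    hit_truth = sum(
        any((p + d, s) in call_set for d in range(-tol, tol + 1))
        for p, s in truth_set)
    hit_calls = sum(
        any((p + d, s) in truth_set for d in range(-tol, tol + 1))
        for p, s in call_set)
    sens = hit_truth / len(truth_set) if truth_set else 1.0
    prec = hit_calls / len(call_set) if call_set else 1.0
    return sens, prec
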