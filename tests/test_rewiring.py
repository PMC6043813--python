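import numpy as np
import pytest
from scipy import stats

from topoplast.rewiring import (RewiringParams, attempt_rewiring,
                                attempts_per_step, bin_events,
                                formation_probability, select_partner)
from topoplast.synapses import SOURCE, TARGET, SynapticSlotTable
from topoplast.topology import GridLayer, pairwise_sq_distances


class ScriptedRNG:
    """Feeds predetermined uniform/integer draws to the attempt logic."""

    def __init__(self, integers=(), randoms=()):
        self._int = list(integers)
        self._rnd = list(randoms)

    def integers(self, *a, **k):
        return self._int.pop(0)

    def random(self, *a, **k):
        return self._rnd.pop(0)


@pytest.mark.parametrize("f_rew, dt, expected", [
    (10_000.0, 1.0, (10, 1)),   # fast: 10 attempts every step
    (100.0, 1.0, (1, 10)),      # slow: one attempt every 10 steps
    (1_000.0, 1.0, (1, 1)),     # boundary between the regimes
    (2_000.0, 0.5, (1, 1)),
])
def test_attempt_schedule(f_rew, dt, expected):
    assert attempts_per_step(f_rew, dt) == expected


def test_attempt_schedule_rejects_bad_rate():
    with pytest.raises(ValueError):
        attempts_per_step(0.0, 1.0)


def test_formation_probability_kernel():
    assert formation_probability(0.0, 2.5, 0.16) == pytest.approx(0.16)
    assert formation_probability(2.5, 2.5, 0.16) == pytest.approx(
        0.16 * np.exp(-0.5))
    assert formation_probability(1.0 * np.sqrt(2), 1.0, 1.0) == pytest.approx(
        np.exp(-1.0))
    with pytest.raises(ValueError):
        formation_probability(1.0, 0.0, 0.5)


def test_partner_selection_uniform_and_abort():
    rng = np.random.default_rng(0)
    assert select_partner([], rng) is None
    assert select_partner([(7, SOURCE)], rng) == (7, SOURCE)
    pool = [(1, SOURCE), (2, SOURCE), (3, TARGET), (200, TARGET)]
    counts = {p: 0 for p in pool}
    n_draw = 100_000
    for _ in range(n_draw):
        counts[select_partner(pool, rng)] += 1
    # uniform to within chi-square at alpha = 1e-3, and each ~25% +- 1%
    chi2 = sum((c - n_draw / 4) ** 2 / (n_draw / 4) for c in counts.values())
    assert chi2 < stats.chi2.ppf(0.999, df=3)
    for c in counts.values():
        assert abs(c / n_draw - 0.25) < 0.01


def test_elimination_of_depressed_synapse(grid16, rewiring_params):
    table = SynapticSlotTable(grid16.n)
    table.add(5, 3, 9, SOURCE, 0.0)
    rng = ScriptedRNG(integers=[5, 3], randoms=[0.02])  # 0.02 < p_elim_dep
    ev = attempt_rewiring(table, rewiring_params, [], rng, 0.0, grid16)
    assert ev.kind == "elimination" and (ev.post_id, ev.slot) == (5, 3)
    assert ev.pre_id == 9 and ev.pre_layer == SOURCE
    assert table.n_synapses() == 0


def test_potentiated_synapse_survives(grid16, rewiring_params):
    table = SynapticSlotTable(grid16.n)
    table.add(5, 3, 9, SOURCE, rewiring_params.g_max)
    rng = ScriptedRNG(integers=[5, 3], randoms=[0.5])   # 0.5 >= p_elim_pot
    ev = attempt_rewiring(table, rewiring_params, [], rng, 0.0, grid16)
    assert ev.kind == "abort"
    assert table.n_synapses() == 1


def test_formation_on_empty_slot_at_zero_distance(grid16, rewiring_params):
    table = SynapticSlotTable(grid16.n)
    # lateral partner at distance 0 (autapse) has acceptance probability 1
    rng = ScriptedRNG(integers=[5, 0, 0], randoms=[0.999999])
    ev = attempt_rewiring(table, rewiring_params, [(5, TARGET)], rng, 2.0,
                          grid16)
    assert ev.kind == "formation"
    assert table.pre[5, 0] == 5 and table.layer[5, 0] == TARGET
    assert table.w[5, 0] == pytest.approx(rewiring_params.g_max)


def test_abort_when_no_spikes(grid16, rewiring_params):
    table = SynapticSlotTable(grid16.n)
    rng = ScriptedRNG(integers=[0, 0])
    ev = attempt_rewiring(table, rewiring_params, [], rng, 0.0, grid16)
    assert ev.kind == "abort"


def test_inhibitory_lateral_formation_flag(grid16, rewiring_params):
    table = SynapticSlotTable(grid16.n)
    rng = ScriptedRNG(integers=[5, 0, 0], randoms=[0.0])
    attempt_rewiring(table, rewiring_params, [(5, TARGET)], rng, 0.0, grid16,
                     lateral_inh=True)
    assert table.is_inh[5, 0]
    rng = ScriptedRNG(integers=[5, 1, 0], randoms=[0.0])
    attempt_rewiring(table, rewiring_params, [(5, SOURCE)], rng, 0.0, grid16,
                     lateral_inh=True)
    assert not table.is_inh[5, 1]   # feedforward stays excitatory


def test_elimination_probability_ratio(rewiring_params):
    """Depressed synapses are pruned about 180x more readily."""
    ratio = rewiring_params.p_elim_dep / rewiring_params.p_elim_pot
    assert ratio == pytest.approx(180, rel=0.01)


def _distance_chisq(d2_to_post, counts_per_sq_dist, p_exact, n_total):
    """Chi-square statistic and dof for counts folded by squared distance."""
    keys = np.unique(d2_to_post)
    obs = np.array([counts_per_sq_dist.get(k, 0) for k in keys], float)
    exp = np.array([p_exact[d2_to_post == k].sum() for k in keys]) * n_total
    keep = exp > 5
    chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
    return chi2, int(keep.sum()) - 1


def test_formation_distance_distribution_matches_torus_gaussian(
        grid16, rewiring_params):
    """Distances accepted by the formation kernel (uniform partner pool)
    follow the Gaussian renormalized over the torus: the acceptance
    probability of every candidate cell is proportional to
    exp(-d^2 / 2 sigma^2)."""
    rng = np.random.default_rng(12)
    d2 = pairwise_sq_distances(grid16)
    sigma, p_form = rewiring_params.sigma_form_ff, rewiring_params.p_form_ff
    p_exact = np.exp(-d2[0] / (2 * sigma ** 2))
    p_exact = p_exact / p_exact.sum()
    # bulk check through the kernel itself, n = 1e5 accepted formations
    cand = rng.integers(grid16.n, size=3_000_000)
    acc = rng.random(cand.size) < formation_probability(
        np.sqrt(d2[0, cand]), sigma, p_form)
    accepted = cand[acc][:100_000]
    counts = dict(zip(*np.unique(d2[0, accepted], return_counts=True)))
    chi2, dof = _distance_chisq(d2[0], counts, p_exact, accepted.size)
    assert chi2 < stats.chi2.ppf(0.999, df=dof)


def test_attempt_rewiring_formation_distances_end_to_end(
        grid16, rewiring_params):
    """Same law through the full attempt path (random posts, spike-pool
    partner selection), folded by each event's own post distance."""
    rng = np.random.default_rng(13)
    d2 = pairwise_sq_distances(grid16)
    sigma = rewiring_params.sigma_form_ff
    p_exact = np.exp(-d2[0] / (2 * sigma ** 2))
    p_exact = p_exact / p_exact.sum()
    pool = [(i, SOURCE) for i in range(grid16.n)]
    table = SynapticSlotTable(grid16.n, s_max=1)
    sq_dists = []
    for _ in range(120_000):
        ev = attempt_rewiring(table, rewiring_params, pool, rng, 0.0, grid16)
        if ev.kind == "formation":
            sq_dists.append(d2[ev.post_id, ev.pre_id])
            table.remove(ev.post_id, ev.slot)
    assert len(sq_dists) > 1500
    counts = dict(zip(*np.unique(sq_dists, return_counts=True)))
    chi2, dof = _distance_chisq(d2[0], counts, p_exact, len(sq_dists))
    assert chi2 < stats.chi2.ppf(0.999, df=dof)


def test_slot_conservation_under_fuzzed_attempts(grid16, rewiring_params):
    rng = np.random.default_rng(3)
    table = SynapticSlotTable(grid16.n, s_max=4)
    pool = [(int(i), int(l)) for i in range(0, 256, 16) for l in (0, 1)]
    for _ in range(20_000):
        attempt_rewiring(table, rewiring_params, pool, rng, 0.0, grid16)
        assert table.occupied.sum(axis=1).max() <= 4
    occ = table.occupied.sum()
    assert 0 < occ <= grid16.n * 4


def test_event_binning():
    from topoplast.rewiring import RewiringEvent
    events = [RewiringEvent(500.0, "formation", 0, 0, 0, 1),
              RewiringEvent(2999.0, "elimination", 0, 0, 0, 1),
              RewiringEvent(3500.0, "formation", 1, 1, 1, 2),
              RewiringEvent(100.0, "abort", 1, 1)]
    df = bin_events(events, bin_s=3.0)
    assert list(df["formations"]) == [1, 1]
    assert list(df["eliminations"]) == [1, 0]
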