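import numpy as np
import pytest

from winfunnel.fixtures import (gen_force_curve, gen_harmonic_trajectory)
from winfunnel.trajectory import (ForceProfile, Trajectory, force_peak,
                                  kabsch_superpose, pull_work,
                                  representative_conformers, rmsd_series,
                                  rmsf_per_residue)


def quaternion_rmsd(ref, mobile):
    """Independent superposition oracle (Horn's quaternion method)."""
    a = ref - ref.mean(axis=0)
    b = mobile - mobile.mean(axis=0)
    m = b.T @ a
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (a ** 2).sum() + (b ** 2).sum()
    msd = max((e0 - 2.0 * lam) / len(a), 0.0)
    return np.sqrt(msd)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def simple_traj(coords):
    n = coords.shape[1]
    return Trajectory(
        coords=coords,
        atom_names=np.array(["CA"] * n),
        chains=np.array(["A"] * n),
        res_ids=np.arange(1, n + 1),
    )


class TestKabsch:
    def test_identical_sets_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 3))
        _, _, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(15, 3))
        _, _, rmsd = kabsch_superpose(x, x + np.array([5.0, 0.0, 0.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 3)) * 5
        for _ in range(5):
            rot = random_rotation(rng)
            t = rng.normal(size=3) * 10
            _, _, rmsd = kabsch_superpose(x, x @ rot.T + t)
            assert rmsd < 1e-8

    def test_matches_quaternion_oracle_with_noise(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(50, 3)) * 4
        mobile = ref + rng.normal(scale=1.0, size=ref.shape)
        rot = random_rotation(rng)
        mobile = mobile @ rot.T + rng.normal(size=3)
        _, _, rmsd = kabsch_superpose(ref, mobile)
        assert rmsd == pytest.approx(quaternion_rmsd(ref, mobile), abs=1e-9)

    def test_proper_rotation(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(10, 3))
        mobile = ref.copy()
        mobile[:, 0] *= -1  # mirrored: best proper fit still det +1
        rot, _, _ = kabsch_superpose(ref, mobile)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line + 1.0)


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self):
        rng = np.random.default_rng(5)
        frame = rng.normal(size=(12, 3))
        traj = simple_traj(np.repeat(frame[None], 6, axis=0))
        assert np.allclose(rmsd_series(traj, selection=np.ones(12, bool)), 0.0)

    def test_single_frame_vs_itself(self):
        rng = np.random.default_rng(6)
        traj = simple_traj(rng.normal(size=(1, 8, 3)))
        out = rmsd_series(traj, selection=np.ones(8, bool))
        assert out.shape == (1,) and out[0] == pytest.approx(0.0, abs=1e-12)

    def test_known_rigid_plus_noise_model(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(40, 3)) * 5
        frames = [ref]
        expected = [0.0]
        for _ in range(4):
            noise = rng.normal(scale=0.5, size=ref.shape)
            rot = random_rotation(rng)
            frames.append((ref + noise) @ rot.T + rng.normal(size=3))
            expected.append(quaternion_rmsd(ref, ref + noise))
        traj = simple_traj(np.array(frames))
        out = rmsd_series(traj, selection=np.ones(40, bool))
        assert np.allclose(out, expected, atol=1e-6)

    def test_empty_selection_rejected(self):
        traj = simple_traj(np.zeros((2, 4, 3)))
        with pytest.raises(ValueError):
            rmsd_series(traj, selection=np.zeros(4, bool))


class TestRmsf:
    def test_static_trajectory_zero(self):
        t = gen_harmonic_trajectory(np.zeros(10), frames=50, seed=0)
        vals = rmsf_per_residue(t, "CA")
        assert all(v == pytest.approx(0.0, abs=1e-10) for v in vals.values())

    def test_sinusoid_amplitude_over_sqrt2(self):
        amps = np.zeros(60)
        amps[[10, 25, 40]] = [2.0, 1.0, 1.5]
        t = gen_harmonic_trajectory(amps, frames=1000, seed=3)
        vals = rmsf_per_residue(t, "CA")
        for idx in (10, 25, 40):
            expected = amps[idx] / np.sqrt(2.0)
            assert vals[("A", idx + 1)] == pytest.approx(expected, rel=0.05)

    def test_amplitude_ratio_linearity(self):
        amps = np.zeros(60)
        amps[[15, 45]] = [1.0, 2.0]
        t = gen_harmonic_trajectory(amps, frames=1000, seed=8)
        vals = rmsf_per_residue(t, "CA")
        ratio = vals[("A", 46)] / vals[("A", 16)]
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_residue_without_side_chain_absent_not_zero(self):
        t = gen_harmonic_trajectory(np.ones(6), frames=40, seed=1,
                                    include_side_chains=True)
        # strip residue 3's CB to emulate glycine
        keep = ~((t.res_ids == 3) & (t.atom_names == "CB"))
        t2 = Trajectory(coords=t.coords[:, keep, :],
                        atom_names=t.atom_names[keep],
                        chains=t.chains[keep], res_ids=t.res_ids[keep])
        side = rmsf_per_residue(t2, "side-chain")
        assert ("A", 3) not in side
        assert ("A", 2) in side

    def test_single_frame_rejected(self):
        t = gen_harmonic_trajectory(np.ones(4), frames=2, seed=0)
        t1 = Trajectory(coords=t.coords[:1], atom_names=t.atom_names,
                        chains=t.chains, res_ids=t.res_ids)
        with pytest.raises(ValueError):
            rmsf_per_residue(t1)


class TestRepresentativeConformers:
    def test_frame_equal_to_average_is_conformer_a(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(20, 3)) * 3
        frames = np.repeat(base[None], 9, axis=0)
        disp = rng.normal(scale=0.5, size=(20, 3))
        # symmetric displacements keep frame 7 exactly at the average
        frames[0] += disp
        frames[1] -= disp
        traj = simple_traj(frames)
        a, b, d = representative_conformers(traj)
        # frames 2..8 sit essentially at the average; 0 and 1 do not
        assert a in range(2, 9) and b in range(2, 9)
        assert max(d[2:]) < min(d[0], d[1])

    def test_planted_distance_ranking(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(30, 3)) * 4
        d1 = rng.normal(size=(30, 3))
        d1 -= d1.mean(axis=0)
        d1 /= np.sqrt((d1 ** 2).sum(axis=1).mean())
        frames = np.array([base + 0.2 * d1, base - 0.2 * d1,
                           base + 0.9 * d1, base - 0.9 * d1])
        traj = simple_traj(frames)
        a, b, d = representative_conformers(traj)
        assert {a, b} == {0, 1}
        assert np.argsort(d)[:2].tolist() == [a, b]

    def test_two_frame_trajectory(self):
        rng = np.random.default_rng(11)
        frames = rng.normal(size=(2, 10, 3))
        a, b, _ = representative_conformers(simple_traj(frames))
        assert {a, b} == {0, 1}

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            representative_conformers(simple_traj(np.zeros((1, 5, 3))))


class TestForcePeak:
    def test_triangular_pulse(self):
        t = np.arange(0.0, 600.0, 1.0)
        f = np.where(t <= 300, 500.0 * t / 300.0,
                     500.0 * (600.0 - t) / 300.0)
        pk, tp = force_peak(ForceProfile(t, f), smoothing_window_ps=0)
        assert (pk, tp) == (500.0, 300.0)

    def test_constant_force_tie_goes_to_first_sample(self):
        t = np.arange(0.0, 10.0, 1.0)
        pk, tp = force_peak(ForceProfile(t, np.full(10, 42.0)))
        assert (pk, tp) == (42.0, 0.0)

    def test_noisy_planted_peak_matches_oracle_smoothing(self):
        profile = gen_force_curve(peak=500.0, t_peak=300.0, noise_sd=25.0,
                                  seed=21)
        window = 10.0
        pk, tp = force_peak(profile, smoothing_window_ps=window)
        # oracle: independent O(n^2) re-smoothing and argmax
        dt = np.median(np.diff(profile.time_ps))
        h = int(round(window / (2 * dt)))
        n = profile.force_kj_nm.size
        sm = np.array([
            profile.force_kj_nm[max(0, i - h):min(n, i + h + 1)].mean()
            for i in range(n)
        ])
        k = int(np.argmax(sm))
        assert pk == pytest.approx(sm[k], abs=1e-9)
        assert tp == pytest.approx(profile.time_ps[k], abs=1e-9)

    def test_zero_noise_exact_recovery(self):
        profile = gen_force_curve(peak=280.0, t_peak=220.0, noise_sd=0.0,
                                  seed=0)
        pk, tp = force_peak(profile)
        assert pk == pytest.approx(280.0, abs=1e-12)
        assert tp == pytest.approx(220.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            force_peak(ForceProfile(np.array([0.0, 1.0]),
                                    np.array([1.0, 2.0])))


class TestPullWork:
    def test_constant_force_closed_form(self):
        t = np.linspace(0.0, 1000.0, 101)
        p = ForceProfile(t, np.full(101, 100.0), velocity_a_ps=0.01)
        # 100 kJ/mol/nm * 0.001 nm/ps * 1000 ps = 100 kJ/mol
        assert pull_work(p) == pytest.approx(100.0, abs=1e-9)

    def test_zero_force_zero_work(self):
        t = np.linspace(0.0, 100.0, 11)
        assert pull_work(ForceProfile(t, np.zeros(11),
                                      velocity_a_ps=0.1)) == 0.0

    def test_work_linear_in_velocity(self):
        rng = np.random.default_rng(12)
        t = np.sort(rng.uniform(0, 500, 40))
        f = rng.uniform(0, 300, 40)
        w1 = pull_work(ForceProfile(t, f, velocity_a_ps=0.1))
        w2 = pull_work(ForceProfile(t, f, velocity_a_ps=0.2))
        assert w2 == pytest.approx(2 * w1)

    def test_piecewise_constant_exact(self):
        t = np.array([0.0, 10.0, 20.0, 40.0])
        f = np.array([50.0, 50.0, 150.0, 150.0])
        p = ForceProfile(t, f, velocity_a_ps=1.0)  # 0.1 nm/ps
        # trapezoid: 50*10 + 100*10 + 150*20 = 4500; x 0.1 nm/ps
        assert pull_work(p) == pytest.approx(450.0, abs=1e-9)

    def test_missing_velocity_rejected(self):
        with pytest.raises(ValueError):
            pull_work(ForceProfile(np.array([0.0, 1.0]),
                                   np.array([1.0, 1.0])))


class TestValidation:
    def test_time_must_increase(self):
        with pytest.raises(ValueError):
            ForceProfile(np.array([0.0, 0.0, 1.0]), np.zeros(3))

    def test_frame_shape_checked(self):
        with pytest.raises(ValueError):
            Trajectory(np.zeros((2, 3)), np.array(["CA"] * 3),
                       np.array(["A"] * 3), np.arange(3))
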