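"""Tract density images, SPAM aggregation, group matrices and the
distance-dependent consensus threshold."""

import numpy as np
import pytest

import connatlas as ca
from connatlas.dissect import SubjectConnectome


def subject_from_pairs(codes, entries):
    """Build a SubjectConnectome from {(i, j): (nos, length)}."""
    codes = np.asarray(codes)
    n = len(codes)
    nos = np.zeros((n, n))
    length = np.zeros((n, n))
    index = {int(c): k for k, c in enumerate(codes)}
    for (i, j), (cnt, ln) in entries.items():
        a, b = index[i], index[j]
        nos[a, b] = nos[b, a] = cnt
        length[a, b] = length[b, a] = ln
    return SubjectConnectome(codes=codes, nos=nos, length=length)


class TestTDI:
    def test_axis_aligned_streamline_hits_centers(self):
        s = np.array([[0.0, 0, 0], [6.0, 0, 0]])
        tdi = ca.compute_tdi([s], (8, 8, 8), np.eye(4))
        hit = np.argwhere(tdi.counts == 1)
        np.testing.assert_array_equal(hit, [[x, 0, 0] for x in range(7)])
        assert tdi.counts.sum() == 7

    def test_duplicate_streamlines_stack(self):
        s = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        tdi = ca.compute_tdi([s, s.copy()], (8, 8, 8), np.eye(4))
        assert tdi.counts.max() == 2
        assert np.all(np.isin(tdi.counts, [0, 2]))

    def test_matches_membership_oracle(self, rng):
        # independent oracles: dense 0.01 mm sampling (lower bound) and
        # exact slab-method segment/voxel-cube intersection (equality)
        bundle = []
        for _ in range(4):
            a = rng.uniform(5, 15, 3)
            b = rng.uniform(25, 40, 3)
            apex = (a + b) / 2 + rng.normal(scale=5, size=3)
            t = np.linspace(0, 1, 40)[:, None]
            bundle.append((1 - t) ** 2 * a + 2 * t * (1 - t) * apex + t**2 * b)
        tdi = ca.compute_tdi(bundle, (48, 48, 48), np.eye(4))

        def slab_voxels(s):
            hit = set()
            for p0, p1 in zip(s[:-1], s[1:]):
                lo = np.floor(np.minimum(p0, p1) + 0.5).astype(int) - 1
                hi = np.floor(np.maximum(p0, p1) + 0.5).astype(int) + 1
                d = p1 - p0
                for vx in range(lo[0], hi[0] + 1):
                    for vy in range(lo[1], hi[1] + 1):
                        for vz in range(lo[2], hi[2] + 1):
                            c = np.array([vx, vy, vz], float)
                            tmin, tmax = 0.0, 1.0
                            ok = True
                            for k in range(3):
                                if d[k] == 0.0:
                                    if not (c[k] - 0.5 <= p0[k] < c[k] + 0.5):
                                        ok = False
                                        break
                                else:
                                    t0 = (c[k] - 0.5 - p0[k]) / d[k]
                                    t1 = (c[k] + 0.5 - p0[k]) / d[k]
                                    tmin = max(tmin, min(t0, t1))
                                    tmax = min(tmax, max(t0, t1))
                            if ok and tmin < tmax:
                                hit.add((vx, vy, vz))
            return hit

        expected = np.zeros((48, 48, 48), dtype=int)
        dense = np.zeros((48, 48, 48), dtype=int)
        for s in bundle:
            for v in slab_voxels(s):
                if all(0 <= c < 48 for c in v):
                    expected[v] += 1
            seg = np.diff(s, axis=0)
            pieces = [s[:1]]
            for k, d in enumerate(seg):
                n = max(int(np.ceil(np.linalg.norm(d) / 0.01)), 1)
                tt = np.linspace(0, 1, n + 1)[1:, None]
                pieces.append(s[k] + tt * d)
            vox = np.unique(np.floor(np.vstack(pieces) + 0.5).astype(int), axis=0)
            vox = vox[np.all((vox >= 0) & (vox < 48), axis=1)]
            dense[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
        np.testing.assert_array_equal(tdi.counts, expected)
        assert np.all(tdi.counts >= dense)  # dense sampling can only undercount

    def test_out_of_grid_samples_ignored(self):
        s = np.array([[-10.0, 0, 0], [3.0, 0, 0]])
        tdi = ca.compute_tdi([s], (8, 8, 8), np.eye(4))
        assert tdi.counts.sum() == 4  # voxels 0..3 only


class TestSPAM:
    def _tdi(self, voxels_counts, pair=(1, 2), subject=0):
        counts = np.zeros((6, 6, 6), dtype=int)
        for v, c in voxels_counts.items():
            counts[v] = c
        return ca.TDIVolume(counts=counts, affine=np.eye(4), pair=pair,
                            subject_id=subject)

    def test_single_subject_probability_one(self):
        spam, mean_tdi = ca.build_spam([self._tdi({(1, 1, 1): 3})])
        assert spam.nsubjects == 1
        np.testing.assert_array_equal(spam.voxels, [[1, 1, 1]])
        np.testing.assert_array_equal(spam.counts, [1])
        assert spam.probabilities[0] == 1.0
        assert mean_tdi[1, 1, 1] == 3.0

    def test_partial_subject_coverage(self):
        tdis = [self._tdi({(2, 2, 2): 1}), self._tdi({(2, 2, 2): 4}),
                self._tdi({(3, 3, 3): 1})]
        spam, mean_tdi = ca.build_spam(tdis)
        probs = dict(zip(map(tuple, spam.voxels), spam.probabilities))
        assert probs[(2, 2, 2)] == pytest.approx(2 / 3)
        assert probs[(3, 3, 3)] == pytest.approx(1 / 3)
        assert mean_tdi[2, 2, 2] == pytest.approx(5 / 3)

    def test_support_is_union_of_subject_supports(self, phantom20, atlas20):
        # brute force on the phantom: recompute each subject's coverage
        ds = phantom20
        pair = atlas20.pairs[0]
        union = {}
        for t in ds.tractograms:
            bundles, _ = ca.extract_bundles(t, ds.parcellation)
            tdi = ca.compute_tdi(bundles.pair_map[pair], t.grid_dim, t.affine,
                                 t.grid_voxsize)
            for v in map(tuple, np.argwhere(tdi.counts >= 1)):
                union[v] = union.get(v, 0) + 1
        spam = atlas20.spams[pair]
        got = dict(zip(map(tuple, spam.voxels), spam.counts))
        assert got == union

    def test_probabilities_in_unit_interval(self, atlas20):
        for spam in atlas20.spams.values():
            p = spam.probabilities
            assert np.all(p > 0) and np.all(p <= 1)

    def test_grid_mismatch_rejected(self):
        a = self._tdi({(1, 1, 1): 1})
        b = ca.TDIVolume(counts=np.zeros((3, 3, 3), dtype=int),
                         affine=np.eye(4), pair=(1, 2))
        with pytest.raises(ValueError):
            ca.build_spam([a, b])


class TestGroupConnectivity:
    codes = [1, 2, 3, 4]

    def test_duplicated_subject(self):
        s = subject_from_pairs(self.codes, {(1, 2): (4, 30.0)})
        g = ca.group_connectivity([s] * 5)
        i, j = g.index_of(1), g.index_of(2)
        assert g.consistency[i, j] == 5
        assert g.numbStlines[i, j] == 4.0
        assert g.length[i, j] == 30.0

    def test_two_subject_arithmetic(self):
        s1 = subject_from_pairs(self.codes, {(1, 2): (4, 30.0)})
        s2 = subject_from_pairs(self.codes, {})
        g = ca.group_connectivity([s1, s2])
        i, j = g.index_of(1), g.index_of(2)
        assert g.consistency[i, j] == 1
        assert g.numbStlines[i, j] == 2.0
        assert g.length[i, j] == 30.0  # mean over subjects having it

    def test_three_subject_spreadsheet_oracle(self):
        # hand computation: (1,3) in subjects 1 and 3 with nos 5,1 and
        # lengths 50,54 -> consistency 2, mean nos 2, mean length 52
        s1 = subject_from_pairs(self.codes, {(1, 3): (5, 50.0), (1, 2): (2, 20.0)})
        s2 = subject_from_pairs(self.codes, {(1, 2): (1, 24.0)})
        s3 = subject_from_pairs(self.codes, {(1, 3): (1, 54.0)})
        g = ca.group_connectivity([s1, s2, s3])
        i, j = g.index_of(1), g.index_of(3)
        assert g.consistency[i, j] == 2
        assert g.numbStlines[i, j] == pytest.approx(2.0)
        assert g.length[i, j] == pytest.approx(52.0)
        a, b = g.index_of(1), g.index_of(2)
        assert g.consistency[a, b] == 2
        assert g.numbStlines[a, b] == pytest.approx(1.0)
        assert g.length[a, b] == pytest.approx(22.0)

    def test_inconsistent_regions_rejected(self):
        s1 = subject_from_pairs([1, 2], {})
        s2 = subject_from_pairs([1, 3], {})
        with pytest.raises(ValueError):
            ca.group_connectivity([s1, s2])


HEMIS = {1: "L", 2: "L", 3: "R", 4: "R"}


def consensus_instance():
    """The hand-evaluated 3-subject, 6-edge consensus instance."""
    codes = [1, 2, 3, 4]
    s1 = subject_from_pairs(codes, {
        (1, 2): (4, 30.0), (3, 4): (3, 40.0), (1, 3): (5, 50.0),
        (1, 4): (2, 80.0), (2, 4): (1, 70.0),
    })
    s2 = subject_from_pairs(codes, {
        (1, 2): (2, 30.0), (1, 3): (5, 50.0), (1, 4): (1, 80.0),
        (2, 3): (1, 60.0), (2, 4): (2, 70.0),
    })
    s3 = subject_from_pairs(codes, {
        (1, 2): (1, 30.0), (1, 3): (5, 50.0), (2, 4): (3, 70.0),
    })
    return [s1, s2, s3]


class TestConsensusThreshold:
    def test_complete_cohort_retains_everything(self):
        codes = [1, 2, 3, 4]
        entries = {(i, j): (2, 10.0 * (i + j)) for i in codes for j in codes if i < j}
        subs = [subject_from_pairs(codes, entries) for _ in range(3)]
        g = ca.group_connectivity(subs)
        retained = ca.consensus_threshold(subs, g, HEMIS, c_min=0.0, n_bins=2)
        assert retained == set(entries)

    def test_cmin_one_bounds_to_unanimous_pairs(self):
        subs = consensus_instance()
        g = ca.group_connectivity(subs)
        retained = ca.consensus_threshold(subs, g, HEMIS, c_min=1.0, n_bins=2)
        unanimous = {(1, 2), (1, 3), (2, 4)}
        assert retained <= unanimous

    def test_hand_evaluated_instance(self):
        # worked by hand: intra bins {30}|{40} with targets 1|0 keep (1,2);
        # inter bins {50,60}|{70,80} with targets 1|2 keep (1,3) and both
        # of (2,4), (1,4)
        subs = consensus_instance()
        g = ca.group_connectivity(subs)
        retained = ca.consensus_threshold(subs, g, HEMIS, c_min=0.0, n_bins=2)
        assert retained == {(1, 2), (1, 3), (1, 4), (2, 4)}

    def test_deterministic(self):
        subs = consensus_instance()
        g = ca.group_connectivity(subs)
        a = ca.consensus_threshold(subs, g, HEMIS, c_min=0.0, n_bins=2)
        b = ca.consensus_threshold(subs, g, HEMIS, c_min=0.0, n_bins=2)
        assert a == b

    def test_retained_pairs_observed_when_cmin_positive(self):
        subs = consensus_instance()
        g = ca.group_connectivity(subs)
        retained = ca.consensus_threshold(subs, g, HEMIS, c_min=0.4, n_bins=2)
        for i, j in retained:
            assert g.consistency[g.index_of(i), g.index_of(j)] >= 2

    def test_density_matches_mean_subject_density(self):
        # stochastic-presence phantom: retained count per class within
        # 2 * n_bins edges of the mean per-subject connection count
        spec = ca.PhantomSpec(seed=3)
        for e in spec.edges:
            e.presence_prob = 0.6
        ds = ca.make_phantom_dataset(spec, 20, with_scalars=False)
        subs = [ca.extract_bundles(t, ds.parcellation)[1] for t in ds.tractograms]
        g = ca.group_connectivity(subs)
        hemis = {int(r["code"]): r["hemisphere"]
                 for _, r in ds.parcellation.table.iterrows()}
        n_bins = 2
        retained = ca.consensus_threshold(subs, g, hemis, c_min=0.0, n_bins=n_bins)

        def cls(pair):
            hi, hj = hemis[pair[0]], hemis[pair[1]]
            return "intra" if hi == hj else "inter"

        for klass in ("intra", "inter"):
            got = sum(1 for p in retained if cls(p) == klass)
            per_subject = []
            for s in subs:
                cnt = 0
                for a in range(len(s.codes)):
                    for b in range(a + 1, len(s.codes)):
                        pair = (int(s.codes[a]), int(s.codes[b]))
                        if s.nos[a, b] > 0 and cls(pair) == klass:
                            cnt += 1
                per_subject.append(cnt)
            assert abs(got - np.mean(per_subject)) <= 2 * n_bins


class TestAssembleAtlas:
    def test_missing_spam_rejected(self, atlas20):
        with pytest.raises(ValueError):
            ca.assemble_atlas(atlas20.header, atlas20.matrices,
                              {}, {atlas20.pairs[0]})

    def test_empty_retained_set_gives_empty_atlas(self, atlas20):
        a = ca.assemble_atlas(atlas20.header, atlas20.matrices,
                              dict(atlas20.spams), set())
        assert a.n_bundles == 0

    def test_bundle_count_equals_retained_set(self, atlas20, phantom20):
        truth = set(
            zip(phantom20.ground_truth["code_i"].astype(int),
                phantom20.ground_truth["code_j"].astype(int))
        )
        assert set(atlas20.pairs) == truth
        assert atlas20.n_bundles == len(truth)


class TestDensityArithmetic:
    def test_region_bookkeeping(self):
        assert ca.multiscale_region_count(68) == 95
        assert ca.multiscale_region_count(446) == 473

    def test_complete_graph_is_hundred_percent(self):
        assert ca.connectivity_density(10, 45) == 100.0

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            ca.connectivity_density(1, 0)
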