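import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pseudomut import ExpressionMatrix, ProbeAnnotation
from pseudomut.pds import (
    compute_pds,
    differential_pds,
    fit_principal_curve,
    leaf_order,
    member_gene_followup,
    select_top_varying_probes,
    stability_filter,
)
from pseudomut.simulate import SyntheticConfig, generate_dataset


def _em_ann(values, genes=None):
    values = np.asarray(values, dtype=float)
    probes = [f"P{i:03d}" for i in range(values.shape[0])]
    samples = [f"S{i:03d}" for i in range(values.shape[1])]
    em = ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples))
    genes = genes or [f"G{i:03d}" for i in range(values.shape[0])]
    ann = ProbeAnnotation(pd.Series(genes, index=pd.Index(probes, name="probe_id")))
    return em, ann


class TestTopVarying:
    def test_all_probes_when_n_large(self, rng):
        em, _ = _em_ann(rng.normal(size=(5, 10)))
        assert set(select_top_varying_probes(em, 100)) == set(em.probe_ids)

    def test_higher_variance_wins(self, rng):
        values = np.vstack([2.0 * rng.normal(size=20), 0.5 * rng.normal(size=20)])
        em, _ = _em_ann(values)
        assert select_top_varying_probes(em, 1) == ["P000"]


class TestPrincipalCurve:
    def test_collinear_points_give_zero_residual(self, rng):
        t = np.sort(rng.uniform(-2, 2, size=40))
        direction = np.array([1.0, 2.0, -0.5])
        points = t[:, None] * direction
        curve = fit_principal_curve(points)
        assert curve.mean_sq_dist == pytest.approx(0.0, abs=1e-10)
        # arc-length coordinate reproduces the ordering of t
        rho = stats.spearmanr(curve.arc_coord, t).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_quadratic_arc_beats_first_pc_line(self, rng):
        """On a noiseless parabola the fitted curve hugs the data more
        tightly than the best straight line (the PCA limit)."""
        t = np.linspace(-1.5, 1.5, 60)
        points = np.column_stack([t, t**2])
        curve = fit_principal_curve(points)
        centered = points - points.mean(axis=0)
        _, s, _ = np.linalg.svd(centered, full_matrices=False)
        pc_msd = (s[1] ** 2) / len(points)  # residual variance off the PC line
        assert curve.mean_sq_dist < pc_msd

    def test_latent_parameter_recovered(self, rng):
        """1-D manifold + noise: the arc-length coordinate tracks the
        generating parameter (Spearman rho >= 0.9)."""
        t = rng.uniform(0, 2, size=120)
        points = np.column_stack([t, 0.5 * t**2, np.sin(t)])
        points += 0.2 * rng.standard_normal(points.shape)
        curve = fit_principal_curve(points)
        rho = abs(stats.spearmanr(curve.arc_coord, t).statistic)
        assert rho >= 0.9

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_principal_curve(rng.normal(size=(5, 3)))


@pytest.fixture(scope="module")
def pathway_data():
    """Synthetic cohort with latent-driven pathway blocks."""
    return generate_dataset(SyntheticConfig(
        n_wt=60, n_mut=25, n_pm=8, n_normal=15,
        n_probes=200, n_informative=10, delta=1.0,
        n_pathways=3, n_noise_pathways=1, pathway_size=10,
        seed=21,
    ))


class TestComputePDS:
    def test_scores_normalized_with_normals_low(self, pathway_data):
        d = pathway_data
        pds = compute_pds(d.pathways["PATHWAY_000"], d.em, d.annotation,
                          d.cohort.normal_ids)
        assert pds.min() == pytest.approx(0.0)
        assert pds.max() == pytest.approx(1.0)
        assert pds.loc[d.cohort.normal_ids].mean() <= pds.mean()

    def test_latent_deregulation_recovered(self, pathway_data):
        d = pathway_data
        pds = compute_pds(d.pathways["PATHWAY_000"], d.em, d.annotation,
                          d.cohort.normal_ids)
        rho = stats.spearmanr(pds.values, d.latent.loc[pds.index].values).statistic
        assert rho >= 0.9

    def test_invariant_to_probe_order_and_affine_rescaling(self, pathway_data):
        d = pathway_data
        genes = d.pathways["PATHWAY_001"]
        base = compute_pds(genes, d.em, d.annotation, d.cohort.normal_ids)
        # permute probe rows and apply a per-probe affine map
        rng = np.random.default_rng(0)
        perm = rng.permutation(d.em.shape[0])
        data = d.em.data.iloc[perm].copy()
        scale = rng.uniform(0.5, 2.0, size=(len(data), 1))
        offset = rng.normal(size=(len(data), 1))
        em2 = ExpressionMatrix(data * scale + offset)
        other = compute_pds(genes, em2, d.annotation, d.cohort.normal_ids)
        np.testing.assert_allclose(other.values, base.values, atol=1e-8)

    def test_linear_case_reduces_to_pc_distance(self, rng):
        """Noiseless linear pathway: PDS equals the normalized first-PC
        coordinate measured from the normal centroid."""
        t = np.concatenate([np.zeros(10), np.sort(rng.uniform(0.5, 3.0, size=40))])
        loadings = np.array([1.0, -0.5, 2.0])
        values = (t[:, None] * loadings).T  # 3 probes x 50 samples
        values += rng.normal(size=(3, 1))  # probe offsets
        em, ann = _em_ann(values)
        normals = em.sample_ids[:10]
        pds = compute_pds(["G000", "G001", "G002"], em, ann, normals)
        expected = (t - t[:10].mean()) / (t - t[:10].mean()).max()
        np.testing.assert_allclose(pds.values, expected, atol=1e-6)

    def test_small_pathway_rejected(self, pathway_data):
        d = pathway_data
        with pytest.raises(ValueError, match="<3"):
            compute_pds(["NOPE"], d.em, d.annotation, d.cohort.normal_ids)


class TestStability:
    def test_manifold_pathway_is_stable(self, pathway_data):
        d = pathway_data
        genes = d.pathways["PATHWAY_000"]
        pds = compute_pds(genes, d.em, d.annotation, d.cohort.normal_ids)
        assert stability_filter(genes, d.em, d.annotation, d.cohort.normal_ids,
                                pds, n_subsamples=8, seed=0)

    def test_noise_pathway_is_unstable(self, pathway_data):
        d = pathway_data
        genes = d.pathways["NOISE_PATHWAY_000"]
        pds = compute_pds(genes, d.em, d.annotation, d.cohort.normal_ids)
        unstable = sum(
            not stability_filter(genes, d.em, d.annotation, d.cohort.normal_ids,
                                 pds, n_subsamples=8, seed=seed)
            for seed in range(5)
        )
        assert unstable >= 4

    def test_zero_subsamples_trivially_stable_with_warning(self, pathway_data):
        d = pathway_data
        genes = d.pathways["PATHWAY_000"]
        pds = compute_pds(genes, d.em, d.annotation, d.cohort.normal_ids)
        with pytest.warns(UserWarning):
            assert stability_filter(genes, d.em, d.annotation,
                                    d.cohort.normal_ids, pds, n_subsamples=0)


class TestDifferentialPDS:
    def test_identical_groups_yield_nothing(self, rng):
        pds = pd.DataFrame(rng.uniform(size=(20, 40)),
                           columns=[f"S{i:03d}" for i in range(40)])
        res = differential_pds(pds, pds.columns[:20], pds.columns[20:], q=0.05)
        assert res["fdr_significant"].sum() <= 1

    def test_planted_shift_detected_with_fdr_control(self):
        """30 shifted pathways among 300: high power, few false flags."""
        detected, false_flags = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_path, n = 300, 80
            scores = rng.normal(size=(n_path, n))
            scores[:30, 40:] += 1.5
            pds = pd.DataFrame(scores, columns=[f"S{i:03d}" for i in range(n)])
            res = differential_pds(pds, pds.columns[:40], pds.columns[40:], q=0.05)
            flags = res["fdr_significant"].to_numpy()
            detected.append(flags[:30].sum())
            false_flags.append(flags[30:].mean())
        assert np.mean(detected) >= 25
        assert np.mean(false_flags) <= 0.05

    def test_zero_variance_pathway_flagged(self):
        pds = pd.DataFrame(np.vstack([np.ones(10), np.random.default_rng(0).uniform(size=10)]),
                           columns=[f"S{i}" for i in range(10)])
        res = differential_pds(pds, pds.columns[:5], pds.columns[5:], q=0.05)
        assert bool(res.loc[0, "zero_variance"])
        assert res.loc[0, "p"] == 1.0


class TestMemberGeneFollowup:
    def test_no_significant_pathways_gives_empty_result(self, pathway_data):
        d = pathway_data
        res = member_gene_followup({}, d.em, d.annotation,
                                   d.em.sample_ids[:10], d.em.sample_ids[10:20])
        assert len(res) == 0

    def test_single_shifted_gene_in_large_union_is_found(self):
        """A one-gene shift inside a ~60-gene union: exactly that gene's
        probes are flagged in most replicates."""
        hits, extras = 0, 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            m, n = 60, 80
            values = rng.normal(size=(m, n))
            values[7, 40:] += 1.5  # the shifted gene's probe
            em, ann = _em_ann(values)
            res = member_gene_followup(
                {"PW": [f"G{i:03d}" for i in range(m)]}, em, ann,
                em.sample_ids[:40], em.sample_ids[40:],
            )
            flagged = set(res.index[res["fdr_significant"]])
            if "P007" in flagged:
                hits += 1
            extras += len(flagged - {"P007"})
        assert hits >= 9
        assert extras / n_seeds <= 1.0

    def test_identical_groups_rarely_flag(self, rng):
        clean = 0
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            em, ann = _em_ann(r.normal(size=(40, 60)))
            res = member_gene_followup({"PW": [f"G{i:03d}" for i in range(40)]},
                                       em, ann, em.sample_ids[:30], em.sample_ids[30:])
            if res["fdr_significant"].sum() == 0:
                clean += 1
        assert clean >= 9


class TestGroupStructure:
    def test_group_mean_ordering_matches_planted_latent(self, pathway_data):
        """Mean PDS per group reproduces the planted ordering
        normal < wt < mut <= PM."""
        d = pathway_data
        table = d.cohort.table
        groups = {
            "normal": d.cohort.normal_ids,
            "wt": [s for s in d.cohort.tumor_ids
                   if table.loc[s, "binary_label"] == "wt" and not table.loc[s, "pm_truth"]],
            "mut": [s for s in d.cohort.tumor_ids if table.loc[s, "binary_label"] == "mut"],
            "PM": d.planted_pm_ids,
        }
        means = {}
        for name in d.pathways:
            if name.startswith("NOISE"):
                continue
            pds = compute_pds(d.pathways[name], d.em, d.annotation, d.cohort.normal_ids)
            for g, ids in groups.items():
                means.setdefault(g, []).append(pds.loc[ids].mean())
        m = {g: np.mean(v) for g, v in means.items()}
        assert m["normal"] < m["wt"] < m["mut"] <= m["PM"]

    def test_leaf_ordering_places_pm_near_mut(self, pathway_data):
        """Hierarchically ordered heatmap columns put planted PM samples
        closer (in rank distance) to the mut block than to the wt block."""
        d = pathway_data
        rows = {
            name: compute_pds(genes, d.em, d.annotation, d.cohort.normal_ids)
            for name, genes in d.pathways.items() if not name.startswith("NOISE")
        }
        pds = pd.DataFrame(rows).T
        order = leaf_order(pds, axis="samples")
        pos = {s: i for i, s in enumerate(order)}
        table = d.cohort.table
        mut_pos = np.mean([pos[s] for s in d.cohort.tumor_ids
                           if table.loc[s, "binary_label"] == "mut"])
        wt_pos = np.mean([pos[s] for s in d.cohort.tumor_ids
                          if table.loc[s, "binary_label"] == "wt"
                          and not table.loc[s, "pm_truth"]])
        pm_dist_mut = np.mean([abs(pos[s] - mut_pos) for s in d.planted_pm_ids])
        pm_dist_wt = np.mean([abs(pos[s] - wt_pos) for s in d.planted_pm_ids])
        assert pm_dist_mut < pm_dist_wt
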