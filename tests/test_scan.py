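"""iLDS scan: window sizing, standardization, significance, sweep calls."""

from dataclasses import replace

import numpy as np
import pytest

from ildscan import scan as sc
from ildscan import simulator as sim
from ildscan.errors import DegenerateScanError, InsufficientDataError
from ildscan.types import (
    GeneModel,
    HaplotypeAlignment,
    LDCurve,
    ScanConfig,
    WindowScore,
)


def curve_from(mids, values):
    mids = np.asarray(mids, float)
    edges = np.concatenate([[mids[0] * 0.9], np.sqrt(mids[:-1] * mids[1:]) * 0 +
                            (mids[:-1] + mids[1:]) / 2, [mids[-1] * 1.1]])
    return LDCurve(edges, mids, np.asarray(values, float),
                   np.full(len(mids), 50))


class TestAutoWindowSize:
    def test_exponential_decay_brackets_half_life(self):
        """r^2(d) = 0.5 exp(-d/1000) + 0.1: the half-way point sits at
        1000 ln 2 ~= 693 bp; the returned size is twice the bracketing bin."""
        mids = np.geomspace(20, 20000, 30)
        vals = 0.5 * np.exp(-mids / 1000.0) + 0.1
        size = sc.auto_window_size(curve_from(mids, vals))
        d_star = size / 2
        below = mids[mids >= 693.0]
        above = mids[mids <= 693.0]
        assert above[-1] <= d_star <= below[1] if len(below) > 1 else True
        assert 500 <= d_star <= 1200

    def test_flat_curve_falls_back_with_warning(self):
        mids = np.geomspace(20, 20000, 12)
        with pytest.warns(UserWarning):
            size = sc.auto_window_size(curve_from(mids, np.full(12, 0.4)))
        assert size == pytest.approx(2 * mids[-1])

    def test_scale_equivariance(self):
        mids = np.geomspace(20, 20000, 30)
        vals = 0.5 * np.exp(-mids / 1000.0) + 0.05
        s1 = sc.auto_window_size(curve_from(mids, vals))
        s2 = sc.auto_window_size(curve_from(mids * 2, vals))
        assert s2 == pytest.approx(2 * s1)

    def test_too_few_bins_rejected(self):
        with pytest.raises(InsufficientDataError):
            sc.auto_window_size(curve_from([10, 100, 1000], [0.5, 0.3, 0.1]))


def make_window(contig="c1", center=0, dns=0.0, dlg=0.0, sig=(True, True),
                span=2000):
    return WindowScore(
        contig_id=contig,
        center_position=center,
        window_start=center - span // 2,
        window_end=center + span // 2,
        r2_dNS=dns,
        r2_dLG=dlg,
        dNS_ci=(dns - 1, dns + 1),
        dLG_ci=(dlg - 1, dlg + 1),
        sig_dNS=sig[0],
        sig_dLG=sig[1],
    )


class TestStandardizeAndScore:
    def test_z_scores_have_zero_mean_unit_variance(self, rng):
        ws = [make_window(center=i * 100, dns=rng.normal(), dlg=rng.normal())
              for i in range(40)]
        out = sc.standardize_and_score(ws)
        z1 = np.array([w.z_dNS for w in out])
        z2 = np.array([w.z_dLG for w in out])
        assert z1.mean() == pytest.approx(0, abs=1e-12)
        assert z1.std() == pytest.approx(1, abs=1e-12)
        assert z2.std() == pytest.approx(1, abs=1e-12)
        for w in out:
            assert w.ilds == pytest.approx(w.z_dNS**2 + w.z_dLG**2)

    def test_outlier_window_scores_high(self, rng):
        ws = [make_window(center=i * 100, dns=rng.normal(), dlg=rng.normal())
              for i in range(60)]
        ws.append(make_window(center=9000, dns=30.0, dlg=30.0))
        out = sc.standardize_and_score(ws)
        assert max(out, key=lambda w: w.ilds).center_position == 9000

    def test_identical_windows_are_degenerate(self):
        ws = [make_window(center=i * 100, dns=1.0, dlg=1.0) for i in range(20)]
        with pytest.raises(DegenerateScanError):
            sc.standardize_and_score(ws)

    def test_fewer_than_ten_windows_rejected(self):
        ws = [make_window(center=i * 100, dns=i, dlg=-i) for i in range(9)]
        with pytest.raises(DegenerateScanError):
            sc.standardize_and_score(ws)


class TestSignificance:
    def _scored(self, rng, n=50):
        ws = [make_window(center=i * 100, dns=rng.normal(), dlg=rng.normal(),
                          sig=(False, False)) for i in range(n)]
        return sc.standardize_and_score(ws)

    def test_component_ci_straddling_zero_blocks_significance(self, rng):
        ws = self._scored(rng)
        top = max(ws, key=lambda w: w.ilds)
        top.sig_dNS, top.sig_dLG = False, True
        out = sc.test_significance(top, ws, ScanConfig())
        assert not out.significant

    def test_top_window_with_both_components_passes(self, rng):
        ws = self._scored(rng)
        top = max(ws, key=lambda w: w.ilds)
        top.sig_dNS = top.sig_dLG = True
        out = sc.test_significance(top, ws, ScanConfig())
        assert out.significant

    def test_subthreshold_window_fails_despite_components(self, rng):
        ws = self._scored(rng)
        mid = sorted(ws, key=lambda w: w.ilds)[len(ws) // 2]
        mid.sig_dNS = mid.sig_dLG = True
        out = sc.test_significance(mid, ws, ScanConfig())
        assert not out.significant


class TestCallSweeps:
    GENES = [
        GeneModel("gA", "c1", 900, 1500, "+", 0),
        GeneModel("gB", "c1", 5000, 5600, "+", 0),
        GeneModel("gC", "c2", 900, 1500, "+", 0),
    ]

    def test_overlapping_windows_merge(self):
        ws = [make_window(center=1000), make_window(center=2000)]
        for w in ws:
            w.significant = True
            w.ilds = 5.0
        calls = sc.call_sweeps(ws, self.GENES)
        assert len(calls) == 1
        assert calls[0].n_windows == 2
        assert calls[0].genes == ["gA"]

    def test_distant_windows_stay_separate(self):
        ws = [make_window(center=1000), make_window(center=20000)]
        for w in ws:
            w.significant = True
            w.ilds = 5.0
        calls = sc.call_sweeps(ws, self.GENES, merge_gap=2000)
        assert len(calls) == 2

    def test_windows_on_different_contigs_never_merge(self):
        ws = [make_window(contig="c1", center=1000),
              make_window(contig="c2", center=1000)]
        for w in ws:
            w.significant = True
            w.ilds = 5.0
        calls = sc.call_sweeps(ws, self.GENES)
        assert len(calls) == 2
        assert {c.contig_id for c in calls} == {"c1", "c2"}
        assert [c.genes for c in sorted(calls, key=lambda c: c.contig_id)] == (
            [["gA"], ["gC"]]
        )

    def test_no_significant_windows_no_calls(self):
        ws = [make_window(center=1000)]
        ws[0].significant = False
        assert sc.call_sweeps(ws, self.GENES) == []

    def test_peak_ilds_recorded(self):
        ws = [make_window(center=1000), make_window(center=1500)]
        ws[0].significant = ws[1].significant = True
        ws[0].ilds, ws[1].ilds = 4.0, 9.0
        calls = sc.call_sweeps(ws, self.GENES)
        assert calls[0].peak_ilds == 9.0


class TestRestandardizationSensitivity:
    def test_removing_nonsignificant_window_keeps_calls(self, rng):
        """Dropping a non-significant window perturbs the genome-wide mean/sd
        (and hence every z-score) slightly, but a clear outlier's sweep call
        survives re-standardization."""
        ws = [make_window(center=i * 300, dns=rng.normal(), dlg=rng.normal(),
                          sig=(False, False)) for i in range(50)]
        ws.append(make_window(center=60_000, dns=25.0, dlg=25.0,
                              sig=(True, True)))
        cfg = ScanConfig()
        full = sc.apply_significance(sc.standardize_and_score(list(ws)), cfg)
        calls_full = sc.call_sweeps(full, [], merge_gap=2000)

        reduced = [w for w in ws if w.center_position != 0]
        # fresh copies: standardization mutates in place
        reduced = [make_window(contig=w.contig_id, center=w.center_position,
                               dns=w.r2_dNS, dlg=w.r2_dLG,
                               sig=(w.sig_dNS, w.sig_dLG)) for w in reduced]
        red = sc.apply_significance(sc.standardize_and_score(reduced), cfg)
        calls_red = sc.call_sweeps(red, [], merge_gap=2000)

        assert [(c.contig_id, c.start, c.end) for c in calls_full] == (
            [(c.contig_id, c.start, c.end) for c in calls_red]
        )
        # the z-scores themselves do shift: re-standardization is global
        z_full = {w.center_position: w.z_dNS for w in full}
        z_red = {w.center_position: w.z_dNS for w in red}
        shared = set(z_full) & set(z_red)
        assert any(abs(z_full[c] - z_red[c]) > 1e-9 for c in shared)


SCAN_SIM = replace(
    sim.BASE_CONFIG,
    Ne=400,
    n_genes=12,
    gene_length=600,
    mu=1.4e-5,
    rho=0.03,
    tract_mean=1500.0,
    burn_in_generations=40,
    sample_size=40,
    seed=5,
)
FAST_SCAN = ScanConfig(seed=3, bootstrap_reps=200, dns_permutations=100,
            max_distance=7000.0)


@pytest.fixture(scope="module")
def small_scan():
    res = sim.simulate(SCAN_SIM)
    result = sc.scan(res.alignment, res.genes, FAST_SCAN)
    return res, result


class TestScanPipeline:
    def test_windows_centered_on_common_nonsyn_snps(self, small_scan):
        from ildscan.io_annotation import call_snvs

        res, result = small_scan
        sites = call_snvs(res.alignment, res.genes)
        eligible = set(
            sites[(sites.maf >= 0.2) & (sites.func_class == "NONSYN")].position
        )
        assert len(result.windows) >= 10
        for w in result.windows:
            assert w.center_position in eligible
            assert w.ilds == pytest.approx(w.z_dNS**2 + w.z_dLG**2)

    def test_deterministic_given_seed(self, small_scan):
        res, result = small_scan
        again = sc.scan(res.alignment, res.genes, FAST_SCAN)
        assert [w.ilds for w in again.windows] == [w.ilds for w in result.windows]
        assert [w.significant for w in again.windows] == (
            [w.significant for w in result.windows]
        )

    def test_invariance_to_haplotype_relabeling(self, small_scan):
        res, result = small_scan
        relabeled = HaplotypeAlignment(
            res.alignment.contig_id,
            res.alignment.matrix,
            [f"x{i}" for i in range(res.alignment.n_haplotypes)],
        )
        other = sc.scan(relabeled, res.genes, FAST_SCAN)
        np.testing.assert_allclose(
            [w.ilds for w in other.windows], [w.ilds for w in result.windows]
        )

    def test_invariance_to_coordinate_translation(self, small_scan):
        """Prepending monomorphic sequence shifts coordinates but not scores."""
        res, result = small_scan
        pad = 500
        n = res.alignment.n_haplotypes
        padded = HaplotypeAlignment(
            res.alignment.contig_id,
            np.concatenate(
                [np.zeros((n, pad), dtype=np.uint8), res.alignment.matrix], axis=1
            ),
            res.alignment.haplotype_ids,
        )
        genes = [
            GeneModel(g.gene_id, g.contig_id, g.start + pad, g.end + pad,
                      g.strand, g.frame_offset)
            for g in res.genes
        ]
        cfg = replace(FAST_SCAN, window_size=result.window_size,
                      max_distance=res.alignment.length / 3)
        base = sc.scan(res.alignment, res.genes, cfg)
        moved = sc.scan(padded, genes, cfg)
        assert [w.center_position + pad for w in base.windows] == (
            [w.center_position for w in moved.windows]
        )
        np.testing.assert_allclose(
            [w.ilds for w in moved.windows],
            [w.ilds for w in base.windows],
            rtol=1e-6,
        )

    def test_duplicating_every_haplotype_leaves_components_unchanged(
        self, small_scan
    ):
        """Window components depend on allele and haplotype frequencies only,
        so doubling the sample by exact duplication changes nothing."""
        from ildscan.io_annotation import call_snvs

        res, result = small_scan
        n = res.alignment.n_haplotypes
        doubled = HaplotypeAlignment(
            res.alignment.contig_id,
            np.vstack([res.alignment.matrix, res.alignment.matrix]),
            res.alignment.haplotype_ids + [f"dup{i}" for i in range(n)],
        )
        sites = call_snvs(res.alignment, res.genes)
        sites2 = call_snvs(doubled, res.genes)
        center = result.windows[0].center_position
        cfg = replace(FAST_SCAN, window_size=result.window_size)
        # rebuild the genome reference curve for each input
        from ildscan import ld_core

        edges = ld_core.log_bin_edges(result.window_size, cfg.n_window_bins,
                                      cfg.min_bin_distance)
        ref1 = sc.genome_reference_curve(
            [sc._contig_context(res.alignment, sites, cfg)], edges,
            cfg.min_pairs_per_bin)
        ref2 = sc.genome_reference_curve(
            [sc._contig_context(doubled, sites2, cfg)], edges,
            cfg.min_pairs_per_bin)
        w1 = sc.window_components(res.alignment, sites, center, cfg, ref1,
                                  window_size=result.window_size,
                                  rng=np.random.default_rng(0))
        w2 = sc.window_components(doubled, sites2, center, cfg, ref2,
                                  window_size=result.window_size,
                                  rng=np.random.default_rng(0))
        assert w1 is not None and w2 is not None
        assert w1.r2_dNS == pytest.approx(w2.r2_dNS, abs=1e-9)
        assert w1.r2_dLG == pytest.approx(w2.r2_dLG, abs=1e-9)

    def test_multi_contig_scan_pools_standardization(self):
        """Windows from all contigs of one genome share the z-standardization
        and threshold, but windows never span contig boundaries."""
        res1 = sim.simulate(replace(SCAN_SIM, seed=21), contig_id="ctg1")
        res2 = sim.simulate(replace(SCAN_SIM, seed=22), contig_id="ctg2")
        genes = res1.genes + res2.genes
        result = sc.scan([res1.alignment, res2.alignment], genes, FAST_SCAN)
        contigs = {w.contig_id for w in result.windows}
        assert contigs == {"ctg1", "ctg2"}
        z = np.array([w.z_dNS for w in result.windows])
        assert z.mean() == pytest.approx(0.0, abs=1e-9)  # pooled, not per-contig
        for call in result.sweeps:
            assert call.contig_id in contigs

    def test_sweeps_bed_round_trip(self, small_scan, tmp_path):
        res, result = small_scan
        ws = list(result.windows)
        for w in ws[:3]:
            w.significant = True
        sweeps = sc.call_sweeps(ws, res.genes, merge_gap=result.window_size)
        path = tmp_path / "sweeps.bed"
        sc.write_sweeps_bed(sweeps, path)
        back = sc.read_sweeps_bed(path)
        assert [(s.contig_id, s.start, s.end, s.n_windows) for s in back] == (
            [(s.contig_id, s.start, s.end, s.n_windows) for s in sweeps]
        )
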