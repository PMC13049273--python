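"""Synthetic phantom / subject / cohort generator contracts."""

import numpy as np
import pandas as pd
import pytest

from gnladc import (AcquisitionSpec, CohortSpec, PhantomSpec, SubjectSpec,
                    bland_altman, default_sites, fit_adc, generate_cohort,
                    generate_phantom, generate_subject, trace_corrector)
from gnladc.roi import GROUP_OF_SITE
from gnladc.simulate import SiteSpec, _SITE_GROUP


def site_center_bias(model, site: SiteSpec, station_offset: float,
                     positioning=np.zeros(3)) -> float:
    """Direct field lookup of the percent bias at a (shifted) site center."""
    p = np.asarray(site.center_mm) + positioning + np.array([0, 0, station_offset])
    return 100.0 * (trace_corrector(model.jacobian(p)) - 1.0)


class TestPhantom:
    def test_determinism_same_seed(self, model):
        spec = PhantomSpec(spacing_mm=8.0, noise_sigma=5.0)
        a = generate_phantom(spec, model, seed=7)
        b = generate_phantom(spec, model, seed=7)
        assert np.array_equal(a.dwi.dw.data, b.dwi.dw.data)
        c = generate_phantom(spec, model, seed=8)
        assert not np.array_equal(a.dwi.dw.data, c.dwi.dw.data)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(noise_sigma=-1.0)

    def test_noiseless_linear_fit_recovers_truth(self, linear_model):
        ph = generate_phantom(PhantomSpec(spacing_mm=8.0), linear_model)
        adc = fit_adc(ph.dwi)
        assert np.allclose(adc.volume.data[ph.mask], 2.13, rtol=1e-6)

    def test_biased_phantom_varies_then_corrects_uniform(self, model):
        ph = generate_phantom(PhantomSpec(spacing_mm=8.0), model)
        adc = fit_adc(ph.dwi)
        vals = adc.volume.data[ph.mask]
        assert vals.max() - vals.min() > 0.05  # spatial bias visible
        cbar = trace_corrector(model.jacobian(ph.dwi.s0.physical_points()))
        corrected = (adc.volume.data / cbar)[ph.mask]
        assert corrected.max() - corrected.min() < 1e-5


class TestSubject:
    def test_trochanter_volume_near_default(self, model):
        spec = SubjectSpec(sites=tuple(default_sites()))
        scan = generate_subject(spec, model, acq=AcquisitionSpec(snr0=0))
        st = scan.stations[1]
        n = int(np.sum(st.labels.volume.data == st.labels.labels["RT"]))
        vol_cm3 = n * st.labels.volume.voxel_volume_mm3 / 1000.0
        assert vol_cm3 == pytest.approx(88.3, abs=10.0)

    def test_zero_jitter_identical_bias_both_timepoints(self, model):
        from gnladc.pipeline import analyze_scan
        spec = SubjectSpec(sites=tuple(default_sites()))
        acq = AcquisitionSpec(snr0=0, spacing_mm=6.0)
        t0 = analyze_scan(generate_subject(spec, model, acq=acq, timepoint=0), model)
        t1 = analyze_scan(generate_subject(spec, model, acq=acq, timepoint=1), model)
        assert np.allclose(t0["bias_mean"], t1["bias_mean"])

    def test_left_shift_breaks_trochanter_symmetry(self, model):
        # subject shifted right (R-L offset < 0): the right trochanter moves
        # farther off-axis where the transverse bias is larger
        from gnladc.pipeline import analyze_scan
        spec = SubjectSpec(sites=tuple(default_sites()),
                           positioning_offset_mm=(-25.0, 0.0, 0.0))
        acq = AcquisitionSpec(snr0=0, spacing_mm=6.0)
        tab = analyze_scan(generate_subject(spec, model, acq=acq), model)
        tab = tab.set_index("site")
        rt, lt = tab.loc["RT", "bias_mean"], tab.loc["LT", "bias_mean"]
        assert rt != pytest.approx(lt, abs=1e-3)
        # sign consistent with direct bias-field lookup at the shifted centers
        sites = {s.label: s for s in spec.sites}
        ref_rt = site_center_bias(model, sites["RT"], spec.station_offsets_mm[1],
                                  np.array([-25.0, 0, 0]))
        ref_lt = site_center_bias(model, sites["LT"], spec.station_offsets_mm[1],
                                  np.array([-25.0, 0, 0]))
        assert (rt > lt) == (ref_rt > ref_lt)

    def test_overlapping_rois_rejected(self, model):
        sites = [s for s in default_sites() if s.label != "LI"]
        bad = SiteSpec(label="LI", center_mm=(-40.0, 30.0, -95.0),
                       semiaxes_mm=(30.0, 24.0, 24.0), true_adc=0.6,
                       fat_fraction=0.2)  # placed on top of RI
        with pytest.raises(ValueError, match="overlap"):
            spec = SubjectSpec(sites=tuple(sites + [bad]))
            generate_subject(spec, model, acq=AcquisitionSpec(snr0=0, spacing_mm=6.0))

    def test_site_volume_outside_factor3_rejected(self):
        sites = list(default_sites())
        huge = SiteSpec(label="RT", center_mm=(-102.0, 0.0, -120.0),
                        semiaxes_mm=(80.0, 80.0, 80.0), true_adc=0.6,
                        fat_fraction=0.2)
        with pytest.raises(ValueError, match="factor-3"):
            SubjectSpec(sites=tuple([huge] + sites[1:]))


class TestBiasSignStructure:
    def test_edge_vertebrae_negative_trochanter_positive(self, model):
        spec = SubjectSpec(sites=tuple(default_sites(include_t11=True)))
        sites = {s.label: s for s in spec.sites}
        ev = [site_center_bias(model, sites[s], spec.station_offsets_mm[0])
              for s in ("T11", "T12", "L1")]
        tr = [site_center_bias(model, sites[s], spec.station_offsets_mm[1])
              for s in ("RT", "LT")]
        assert all(b < 0 for b in ev)
        assert all(b > 0 for b in tr)
        mv = [site_center_bias(model, sites[s], spec.station_offsets_mm[0])
              for s in ("L2", "L3", "L4")]
        assert max(abs(b) for b in mv) < 2.0  # mid-vertebrae near isocenter


class TestNoiselessSubjectPipeline:
    def test_gnc_reduces_site_mean_bias_everywhere(self, model):
        from gnladc.pipeline import analyze_scan
        spec = SubjectSpec(sites=tuple(default_sites()))
        acq = AcquisitionSpec(snr0=0)  # noiseless
        tab = analyze_scan(generate_subject(spec, model, acq=acq), model)
        tab = tab.merge(
            pd.DataFrame([{"site": s.label, "true_adc": s.true_adc}
                          for s in spec.sites]),
            on="site")
        pct_u = 100 * (tab["adc_mean"] / tab["true_adc"] - 1)
        pct_c = 100 * (tab["adc_gnc_mean"] / tab["true_adc"] - 1)
        assert np.all(np.abs(pct_c) <= 0.1)
        assert np.all(np.abs(pct_c) <= np.abs(pct_u) + 1e-9)
        assert np.abs(pct_u).max() > 1.0  # uncorrected visibly biased

    def test_roi_bias_mean_matches_analytic_ellipsoid_mean(self, model):
        # volume-weighted mean of the bias field over the labelled ellipsoid,
        # via dense independent sampling, within discretization error
        from gnladc.pipeline import analyze_scan
        spec = SubjectSpec(sites=tuple(default_sites()))
        acq = AcquisitionSpec(snr0=0)
        tab = analyze_scan(generate_subject(spec, model, acq=acq), model)
        tab = tab.set_index("site")
        rng = np.random.default_rng(11)
        for label in ("RT", "T12", "L5"):
            site = next(s for s in spec.sites if s.label == label)
            u = rng.uniform(-1, 1, size=(20000, 3))
            u = u[np.sum(u**2, axis=1) <= 1.0]
            pts = (np.asarray(site.center_mm) + u * np.asarray(site.semiaxes_mm)
                   + np.array([0, 0, spec.station_offsets_mm[
                       1 if label in ("RT", "LT", "RI", "LI") else 0]]))
            analytic = 100.0 * (trace_corrector(model.jacobian(pts)) - 1.0).mean()
            assert tab.loc[label, "bias_mean"] == pytest.approx(analytic, abs=0.2)


class TestCohort:
    def test_determinism_and_seed_sensitivity(self, model):
        spec = CohortSpec(n_subjects=2, n_timepoints=1, seed=3,
                          acquisition=AcquisitionSpec(spacing_mm=6.0))
        a = generate_cohort(spec, model)
        b = generate_cohort(spec, model)
        assert a.truth.equals(b.truth)
        sa = a.scans[0][0].stations[0].dwi.dw.data
        sb = b.scans[0][0].stations[0].dwi.dw.data
        assert np.array_equal(sa, sb)
        c = generate_cohort(CohortSpec(n_subjects=2, n_timepoints=1, seed=4,
                                       acquisition=AcquisitionSpec(spacing_mm=6.0)),
                            model)
        assert not np.array_equal(sa, c.scans[0][0].stations[0].dwi.dw.data)

    def test_low_ff_count_by_construction(self, model):
        from gnladc import select_subjects
        spec = CohortSpec(n_subjects=8, n_timepoints=1, seed=5, n_low_ff=5,
                          acquisition=AcquisitionSpec(spacing_mm=8.0, snr0=0))
        cohort = generate_cohort(spec, model)
        kept = select_subjects(cohort.truth, ff_limit=0.40)
        assert len(kept) == 5

    def test_zero_jitter_gives_zero_bias_loa(self, model):
        from gnladc.pipeline import bland_altman_by_site, build_cohort_table
        spec = CohortSpec(
            n_subjects=3, n_timepoints=2, seed=6,
            jitter_sigma_mm=(0.0, 0.0, 0.0), vertebra_shift_prob=0.0,
            subject_offset_sigma_mm=(0.0, 0.0, 0.0),
            acquisition=AcquisitionSpec(spacing_mm=6.0, snr0=0),
        )
        cohort = generate_cohort(spec, model)
        table = build_cohort_table(cohort, model)
        pooled, _ = bland_altman_by_site(table, "bias_mean")
        assert pooled.loa_halfwidth == 0.0
        assert pooled.mean_diff == 0.0


class TestJitterToBiasCalibration:
    def test_mc_loa_within_ci_of_linearized_closed_form(self, model):
        """33 test-retest pairs of site-center bias under default jitter vs
        the 1.96*sigma_diff implied by the local bias-field sensitivity."""
        spec = CohortSpec(seed=0)
        sites = {s.label: s for s in default_sites()}
        rng = np.random.default_rng(42)
        sig = np.asarray(spec.jitter_sigma_mm)
        for label in ("L1", "T12", "RT"):
            site = sites[label]
            st_off = spec.station_offsets_mm if hasattr(spec, "station_offsets_mm") \
                else (10.0, 130.0)
            offset = st_off[0] if GROUP_OF_SITE[label] in ("MV", "EV") else st_off[1]
            # linearized sensitivity of bias to position at the site center
            grad = np.array([
                (site_center_bias(model, site, offset, dp) -
                 site_center_bias(model, site, offset, -dp)) / (2 * h)
                for h, dp in [(1.0, np.array([1.0, 0, 0])),
                              (1.0, np.array([0, 1.0, 0])),
                              (1.0, np.array([0, 0, 1.0]))]
            ])
            var_axis = sig**2
            # S-I jitter mixes a +/- one-vertebra landmark shift
            var_axis = var_axis.copy()
            var_axis[2] += spec.vertebra_shift_prob * spec.vertebra_pitch_mm**2
            sigma_bias = np.sqrt(np.sum(grad**2 * var_axis))
            sigma_diff = np.sqrt(2) * sigma_bias

            diffs = []
            for _ in range(33):
                js = []
                for _ in range(2):
                    j = rng.normal(0.0, sig)
                    if rng.random() < spec.vertebra_shift_prob:
                        j[2] += spec.vertebra_pitch_mm * (1 if rng.random() < 0.5 else -1)
                    js.append(site_center_bias(model, site, offset, j))
                diffs.append(js[0] - js[1])
            res = bland_altman(np.array(diffs), np.zeros(33))
            # 99.9% chi-square CI for a sample SD at n-1 dof, plus slack for
            # linearization error over the 32 mm landmark shifts
            from scipy.stats import chi2
            lo = np.sqrt(chi2.ppf(0.0005, 32) / 32) * sigma_diff
            hi = np.sqrt(chi2.ppf(0.9995, 32) / 32) * sigma_diff
            assert 1.96 * lo * 0.8 <= res.loa_halfwidth <= 1.96 * hi * 1.2


def test_cohort_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(n_subjects=0)
    with pytest.raises(ValueError):
        CohortSpec(vertebra_shift_prob=1.5)
    with pytest.raises(ValueError):
        CohortSpec(jitter_sigma_mm=(-1.0, 0.0, 0.0))
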