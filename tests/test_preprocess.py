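"""Baseline correction, region selection, normalization, assembly."""

import numpy as np
import pytest

from hypospec import (
    AslsParams,
    GeneratorConfig,
    RegionSet,
    Spectrum,
    WavenumberGrid,
    assemble_matrix,
    default_band_library,
    mean_center,
    normalize_unit_area,
    select_regions,
    subtract_baseline,
    synth_dataset,
)
from hypospec.preprocess import (
    asls_baseline,
    normalize_dataset,
    polyfit_baseline,
    polyfit_baseline_matrix,
    _second_difference_banded,
)
from hypospec.pipeline import PipelineConfig, baseline_correct_dataset
from hypospec.synth import lorentzian


# ---------------------------------------------------------------- polyfit


def test_polyfit_fixed_point_on_pure_polynomial():
    x = np.linspace(0, 10, 300)
    y = 1.0 + 0.5 * x - 0.2 * x**2 + 0.03 * x**3 - 1e-3 * x**4 + 5e-5 * x**5
    base = polyfit_baseline(y, x, order=5)
    assert np.max(np.abs(base - y)) <= 1e-8 * np.max(np.abs(y))


def test_polyfit_constant_with_order_zero():
    y = np.full(50, 3.7)
    base = polyfit_baseline(y, order=0)
    assert np.allclose(base, 3.7)


def test_polyfit_recovers_peak_on_polynomial_background():
    x = np.linspace(200, 3400, 3180)
    bg = 50 + 0.01 * x + 2e-6 * (x - 1500) ** 2
    peak = 5.0 * lorentzian(x - 1007.0, 12.0)
    base = polyfit_baseline(bg + peak, x, order=5)
    corrected = bg + peak - base
    i = np.argmin(np.abs(x - 1007.0))
    assert corrected[i] == pytest.approx(peak.max(), rel=0.05)


def test_polyfit_clipped_signal_is_pointwise_nonincreasing(rng):
    y = rng.normal(size=400).cumsum()  # rough, drifting signal
    _, history = polyfit_baseline(y, order=5, max_iter=30, return_history=True)
    work = y.copy()
    prev = work
    for fit in history[:-1]:
        work = np.minimum(work, fit)
        assert np.all(work <= prev + 1e-12)
        prev = work


def test_polyfit_rejects_nonfinite_and_short_input():
    with pytest.raises(ValueError):
        polyfit_baseline(np.array([1.0, np.nan, 2.0, 3.0] * 5), order=2)
    with pytest.raises(ValueError):
        polyfit_baseline(np.arange(4.0), order=5)


def test_polyfit_matrix_matches_per_row(rng):
    x = np.linspace(0, 100, 250)
    Y = np.vstack(
        [
            10 + 0.1 * x + 3 * lorentzian(x - 30, 4.0) + rng.normal(0, 0.05, x.size)
            for _ in range(5)
        ]
    )
    batch = polyfit_baseline_matrix(Y, x, order=3)
    for i in range(Y.shape[0]):
        single = polyfit_baseline(Y[i], x, order=3)
        assert np.allclose(batch[i], single, atol=1e-10)


# ------------------------------------------------------------------ AsLS


def _asls_dense_oracle(y, params):
    """Straight dense-matrix replication of the AsLS iterations."""
    n = y.size
    D = np.diff(np.eye(n), n=2, axis=0)
    penalty = params.lam * (D.T @ D)
    w = np.ones(n)
    z = y
    for _ in range(params.n_iter):
        A = np.diag(w) + penalty
        z = np.linalg.solve(A, w * y)
        w = np.where(y > z, params.p, 1.0 - params.p)
    return z


def test_asls_flat_signal_is_exact_fixed_point():
    y = np.full(200, 2.5)
    z = asls_baseline(y, AslsParams(lam=1e5, p=0.01, n_iter=5))
    assert np.max(np.abs(z - 2.5)) <= 1e-8


@pytest.mark.parametrize("n,lam,p", [(50, 1e2, 0.01), (120, 1e5, 0.001), (200, 1e4, 0.05)])
def test_asls_banded_solve_matches_dense_oracle(rng, n, lam, p):
    x = np.linspace(0, 1, n)
    y = np.sin(3 * x) + 5 * np.exp(-((x - 0.5) ** 2) / 1e-3) + rng.normal(0, 0.05, n)
    params = AslsParams(lam=lam, p=p, n_iter=10)
    assert np.max(np.abs(asls_baseline(y, params) - _asls_dense_oracle(y, params))) <= 1e-8


def test_asls_small_lambda_tracks_smooth_signal():
    x = np.linspace(0, 4 * np.pi, 400)
    y = np.sin(x)
    dev = [
        np.max(np.abs(asls_baseline(y, AslsParams(lam=lam, p=0.4999, n_iter=1)) - y))
        for lam in (1e2, 1e0, 1e-2)
    ]
    assert dev[0] > dev[1] > dev[2]
    assert dev[-1] < 1e-3


def test_asls_baseline_stays_below_peak(rng):
    x = np.linspace(0, 1, 500)
    y = 10 * np.exp(-((x - 0.5) ** 2) / 2e-4) + rng.normal(0, 0.01, x.size)
    z = asls_baseline(y, AslsParams(lam=1e5, p=0.001, n_iter=10))
    frac_above = np.mean(z > y + 0.03)  # 3x noise floor
    assert frac_above <= 0.05


def test_asls_parameter_validation():
    with pytest.raises(ValueError):
        AslsParams(lam=0.0)
    with pytest.raises(ValueError):
        AslsParams(p=0.5)
    with pytest.raises(ValueError):
        AslsParams(p=0.0)
    with pytest.raises(ValueError):
        asls_baseline(np.array([1.0, 2.0]))


def test_second_difference_banded_matches_dense():
    n = 17
    D = np.diff(np.eye(n), n=2, axis=0)
    dense = D.T @ D
    ab = _second_difference_banded(n)
    assert np.allclose(ab[2], np.diag(dense))
    assert np.allclose(ab[1, 1:], np.diag(dense, 1))
    assert np.allclose(ab[0, 2:], np.diag(dense, 2))


# ------------------------------------------------------- subtract_baseline


def test_subtract_baseline_properties():
    grid = WavenumberGrid.uniform(0, 10, 20)
    s = Spectrum(grid, np.arange(20.0), meta={"class": "CTRL", "map_id": "m"})
    assert np.array_equal(subtract_baseline(s, np.zeros(20)).intensities, s.intensities)
    assert np.allclose(subtract_baseline(s, s.intensities).intensities, 0.0)
    a, b = np.full(20, 1.0), np.full(20, 2.0)
    seq = subtract_baseline(subtract_baseline(s, a), b)
    joint = subtract_baseline(s, a + b)
    assert np.allclose(seq.intensities, joint.intensities)
    assert seq.meta["map_id"] == "m"
    with pytest.raises(ValueError):
        subtract_baseline(s, np.zeros(19))


# ---------------------------------------------------------- select_regions


def _toy_dataset(n_channels=3180):
    cfg = GeneratorConfig(
        n_maps_per_class=1, spectra_per_map=2, grid=(200, 3400, n_channels),
        noise_sd=0.0, bg_amp_range=(0.0, 0.0), bg_offset_range=(0.0, 0.0),
    )
    return synth_dataset(cfg, default_band_library())


def test_select_regions_matches_bruteforce_channel_scan():
    ds = _toy_dataset()
    regions = RegionSet(intervals=((500.0, 1800.0), (2100.0, 3100.0)))
    out = select_regions(ds, regions)
    expected = sum(
        1
        for w in ds.grid.values
        if (500 <= w <= 1800) or (2100 <= w <= 3100)
    )
    assert out.n_channels == expected
    assert len(out.segments) == 2
    assert np.all(np.diff(out.grid.values) > 0)


def test_select_regions_full_span_is_identity():
    ds = _toy_dataset(400)
    out = select_regions(ds, RegionSet(intervals=((0.0, 4000.0),)))
    assert np.array_equal(out.matrix, ds.matrix)
    assert out.grid == ds.grid


def test_select_regions_single_channel_and_empty():
    ds = _toy_dataset(400)
    w = float(ds.grid.values[37])
    out = select_regions(ds, RegionSet(intervals=((w, w + 1e-9),)))
    assert out.n_channels == 1
    with pytest.raises(ValueError):
        select_regions(ds, RegionSet(intervals=((w + 1e-6, w + 1e-3),)))


def test_region_set_validation_and_parsing():
    with pytest.raises(ValueError):
        RegionSet(intervals=((10.0, 5.0),))
    with pytest.raises(ValueError):
        RegionSet(intervals=((0.0, 10.0), (5.0, 20.0)))
    rs = RegionSet.parse("500-1800,2100-3100")
    assert rs.intervals == ((500.0, 1800.0), (2100.0, 3100.0))
    with pytest.raises(ValueError):
        RegionSet.parse("nonsense")


# ------------------------------------------------------------ normalization


def test_normalize_constant_spectrum():
    grid = WavenumberGrid.uniform(0, 10, 11)
    s = Spectrum(grid, np.full(11, 2.0))
    out = normalize_unit_area(s)
    assert np.allclose(out.intensities, 0.1)


def test_normalize_is_idempotent_and_unit_area(rng):
    grid = WavenumberGrid.uniform(200, 3400, 500)
    s = Spectrum(grid, rng.uniform(0.1, 2.0, 500))
    once = normalize_unit_area(s)
    area = np.trapezoid(once.intensities, grid.values)
    assert area == pytest.approx(1.0, abs=1e-9)
    twice = normalize_unit_area(once)
    assert np.max(np.abs(twice.intensities - once.intensities)) <= 1e-12


def test_normalize_rejects_nonpositive_area():
    grid = WavenumberGrid.uniform(0, 10, 11)
    with pytest.raises(ValueError):
        normalize_unit_area(Spectrum(grid, np.full(11, -1.0)))


def test_normalize_dataset_uses_piecewise_segments():
    ds = _toy_dataset(800)
    ds.matrix += 1.0  # keep areas positive
    cropped = select_regions(ds, RegionSet(intervals=((500.0, 1800.0), (2100.0, 3100.0))))
    out = normalize_dataset(cropped)
    w = out.grid.values
    for row in out.matrix:
        area = sum(
            np.trapezoid(row[lo:hi], w[lo:hi]) for lo, hi in out.segments
        )
        assert area == pytest.approx(1.0, abs=1e-9)


# ------------------------------------------------------------- mean_center


def test_mean_center_train_only_semantics():
    ds = _toy_dataset(400)
    train = ds.subset_rows([0])  # CTRL row
    test = ds.subset_rows([2])  # HFD row
    (train_c, test_c), mean = mean_center(train, test)
    assert np.max(np.abs(train_c.matrix.mean(axis=0))) <= 1e-10
    assert mean.shape == (400,)
    # HFD test row centered by CTRL-only means: generally nonzero
    assert np.abs(test_c.matrix.mean(axis=0)).max() > 0


def test_mean_center_identical_rows_become_zero():
    ds = _toy_dataset(400)
    dup = ds.subset_rows([0, 0])
    (c,), _ = mean_center(dup)
    assert np.allclose(c.matrix, 0.0)


def test_mean_center_grid_mismatch():
    a = _toy_dataset(400)
    b = _toy_dataset(401)
    with pytest.raises(ValueError):
        mean_center(a, b)


# --------------------------------------------------------- assemble_matrix


def _spectra_list():
    grid = WavenumberGrid.uniform(0, 10, 16)
    metas = [
        {"class": "HFD", "map_id": "HFD_map1", "x": 0.0, "y": 0.0},
        {"class": "CTRL", "map_id": "CTRL_map2", "x": 0.0, "y": 0.0},
        {"class": "CTRL", "map_id": "CTRL_map1", "x": 25.0, "y": 0.0},
        {"class": "CTRL", "map_id": "CTRL_map1", "x": 0.0, "y": 0.0},
    ]
    return [
        Spectrum(grid, np.full(16, float(i)), meta=m) for i, m in enumerate(metas)
    ]


def test_assemble_orders_by_class_map_position():
    ds = assemble_matrix(_spectra_list())
    assert list(ds.meta["map_id"]) == ["CTRL_map1", "CTRL_map1", "CTRL_map2", "HFD_map1"]
    assert list(ds.matrix[:, 0]) == [3.0, 2.0, 1.0, 0.0]
    assert list(ds.labels) == ["CTRL", "CTRL", "CTRL", "HFD"]


def test_assemble_single_and_empty():
    single = assemble_matrix(_spectra_list()[:1])
    assert single.matrix.shape == (1, 16)
    with pytest.raises(ValueError):
        assemble_matrix([])


def test_assemble_grid_mismatch_names_map():
    spectra = _spectra_list()
    bad = Spectrum(
        WavenumberGrid.uniform(0, 10, 17), np.zeros(17), meta={"map_id": "ODD_map9"}
    )
    with pytest.raises(ValueError, match="ODD_map9"):
        assemble_matrix(spectra + [bad])


# -------------------------------------------------- end-to-end recovery


def test_band_heights_recovered_through_10x_background():
    """Noiseless spectra under a 10x fluorescence background: two-stage
    correction recovers isolated band heights within 10%."""
    cfg = GeneratorConfig(
        n_maps_per_class=1, spectra_per_map=3, noise_sd=0.0,
        bg_amp_range=(10.0, 10.0), bg_offset_range=(1.0, 1.0), seed=5,
    )
    lib = default_band_library()
    ds = synth_dataset(cfg, lib)
    corr = baseline_correct_dataset(ds, PipelineConfig(generator=cfg))
    w = ds.grid.values
    for cls in ("CTRL", "HFD"):
        truth = lib.evaluate(w, cls)
        row = corr.matrix[corr.rows_for_class(cls)[0]]
        for center in (1007.0, 2248.0, 2850.0):
            i = np.argmin(np.abs(w - center))
            assert row[i] == pytest.approx(truth[i], rel=0.10), (cls, center)
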