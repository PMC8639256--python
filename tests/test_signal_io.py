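import numpy as np
import pandas as pd
import pytest

from copsway.io import (
    CONDITIONS,
    CopTrace,
    ForcePlateRecord,
    FormatError,
    UnstableLoadError,
    compute_cop,
    pool_conditions,
    read_cop,
    read_force_plate,
    read_manifest,
    write_cop,
    write_manifest,
)
from copsway.simulate import to_force_plate


def make_record(n=100, fz=700.0, **channels):
    base = {c: np.zeros(n) for c in ("fx", "fy", "mx", "my", "mz")}
    base["fz"] = np.full(n, fz)
    for name, val in channels.items():
        base[name] = np.asarray(val, float) * np.ones(n) if np.isscalar(val) else np.asarray(val, float)
    return ForcePlateRecord(
        subject_id="S1", group_label="nonfall", condition="OR",
        trial_index=1, sampling_rate=100.0, **base,
    )


class TestComputeCop:
    def test_plate_equations_with_constant_load(self):
        trace = compute_cop(make_record(my=-35.0), center=False)
        assert np.allclose(trace.cop_x, 0.05)
        trace = compute_cop(make_record(mx=14.0), center=False)
        assert np.allclose(trace.cop_y, 0.02)

    def test_origin_height_shifts_by_shear(self):
        rec = make_record(my=-35.0, fx=10.0)
        trace = compute_cop(rec, plate_origin_height=0.05, center=False)
        assert np.allclose(trace.cop_x, (35.0 - 0.5) / 700.0)

    def test_linear_in_moments(self, rng):
        n = 200
        rec = make_record(n, mx=rng.normal(10, 1, n), my=rng.normal(-20, 1, n))
        doubled = make_record(n, mx=2 * rec.mx, my=2 * rec.my)
        t1 = compute_cop(rec, center=False)
        t2 = compute_cop(doubled, center=False)
        assert np.allclose(t2.cop_x, 2 * t1.cop_x)
        assert np.allclose(t2.cop_y, 2 * t1.cop_y)

    def test_unstable_load_reports_sample_index(self):
        fz = np.full(50, 700.0)
        fz[17] = 0.5
        with pytest.raises(UnstableLoadError, match="17"):
            compute_cop(make_record(50, fz=fz))

    def test_centering_default(self):
        trace = compute_cop(make_record(my=-35.0))
        assert abs(trace.cop_x.mean()) < 1e-15


class TestValidation:
    def test_unequal_channel_lengths(self):
        with pytest.raises(FormatError, match="unequal"):
            ForcePlateRecord(
                "S1", "nonfall", "OR", 1, 100.0,
                fx=np.zeros(5), fy=np.zeros(5), fz=np.ones(4),
                mx=np.zeros(5), my=np.zeros(5), mz=np.zeros(5),
            )

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            make_record().__class__(
                "S1", "nonfall", "XX", 1, 100.0,
                **{c: np.zeros(5) for c in ("fx", "fy", "mx", "my", "mz")},
                fz=np.ones(5),
            )

    def test_nonfinite_cop_rejected(self):
        with pytest.raises(FormatError, match="finite"):
            CopTrace("S1", "fall", "CR", 1, 100.0,
                     cop_x=np.array([0.0, np.inf]), cop_y=np.zeros(2))


class TestFileFormats:
    def test_force_plate_csv_roundtrip(self, tmp_path, rng):
        path = tmp_path / "trial.csv"
        df = pd.DataFrame(
            {c: rng.normal(size=60) for c in ("fx", "fy", "mx", "my", "mz")}
        )
        df["fz"] = rng.normal(700, 5, 60)
        df.to_csv(path, index=False)
        rec = read_force_plate(path, "S9", "fall", "CF", 2, 100.0)
        assert rec.n_samples == 60
        assert np.allclose(rec.fz, df["fz"])

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({c: [1.0, 2.0] for c in ("fx", "fy", "fz", "mx", "my")}).to_csv(
            path, index=False
        )
        with pytest.raises(FormatError, match="mz"):
            read_force_plate(path, "S1", "fall", "CR", 1, 100.0)

    def test_too_few_rows(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("fx,fy,fz,mx,my,mz\n")
        with pytest.raises(FormatError, match="2 data rows"):
            read_force_plate(path, "S1", "fall", "CR", 1, 100.0)

    def test_cop_csv_roundtrip_full_precision(self, tmp_path, rng):
        trace = CopTrace(
            "S2", "nonfall", "OF", 3, 100.0,
            cop_x=rng.normal(scale=1e-3, size=500),
            cop_y=rng.normal(scale=1e-3, size=500),
        )
        path = tmp_path / "cop.csv"
        write_cop(trace, path)
        back = read_cop(path, "S2", "nonfall", "OF", 3, 100.0, center=False)
        np.testing.assert_array_equal(back.cop_x, trace.cop_x)
        np.testing.assert_array_equal(back.cop_y, trace.cop_y)

    def test_manifest_roundtrip_both_dialects(self, tmp_path, rng):
        traces = [
            CopTrace(
                f"S{i}", "fall" if i % 2 else "nonfall", cond, 1, 100.0,
                cop_x=c - c.mean(), cop_y=d - d.mean(),
            )
            for i, (cond, c, d) in enumerate(
                (cond, rng.normal(size=300), rng.normal(size=300))
                for cond in CONDITIONS
            )
        ]
        manifest = write_manifest(traces, tmp_path / "cohort")
        back = read_manifest(manifest)
        assert len(back) == len(traces)
        np.testing.assert_allclose(back[0].cop_x, traces[0].cop_x)

        # raw force-plate dialect through the same manifest scheme
        fp_dir = tmp_path / "force"
        fp_dir.mkdir()
        rows = []
        for tr in traces:
            rec = to_force_plate(tr)
            fname = f"{tr.subject_id}.csv"
            pd.DataFrame(
                {c: getattr(rec, c) for c in ("fx", "fy", "fz", "mx", "my", "mz")}
            ).to_csv(fp_dir / fname, index=False, float_format="%.17g")
            rows.append(dict(path=fname, subject_id=tr.subject_id,
                             group=tr.group_label, condition=tr.condition,
                             trial=tr.trial_index, sampling_rate=100.0))
        mpath = fp_dir / "manifest.csv"
        pd.DataFrame(rows).to_csv(mpath, index=False)
        back = read_manifest(mpath)
        np.testing.assert_allclose(back[0].cop_x, traces[0].cop_x, atol=1e-12)


class TestPooling:
    def _traces(self, rng):
        out = []
        for cond in CONDITIONS:
            for trial in (1, 2, 3):
                out.append(
                    CopTrace("S1", "nonfall", cond, trial, 100.0,
                             cop_x=rng.normal(size=20), cop_y=rng.normal(size=20))
                )
        return out

    def test_single_condition_view_filters(self, rng):
        ds = pool_conditions(self._traces(rng), "OR")
        assert len(ds) == 3
        assert all(t.condition == "OR" for t in ds.traces)

    def test_c4_is_union_of_conditions(self, rng):
        traces = self._traces(rng)
        ds = pool_conditions(traces, "C4")
        assert len(ds) == 12
        total = sum(len(ds.view(c)) for c in CONDITIONS)
        assert total == len(ds)

    def test_unknown_selector(self, rng):
        with pytest.raises(ValueError, match="view"):
            pool_conditions(self._traces(rng), "ALL")

    def test_empty_input(self):
        with pytest.raises(ValueError):
            pool_conditions([], "C4")
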