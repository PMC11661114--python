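"""File dialect, unit conversion, and writers."""

import io
import math

import numpy as np
import pytest

from prd import model_io as mio
from prd._units import kon3d_to_internal, copies_to_uM
from prd.validation_observables import BENCHMARKS, build_benchmark


class TestRuleTextParsing:
    def test_reversible_binding_rule(self):
        order, pats, rev, kind = mio.parse_rule_text(
            "A(c) + A(q) <-> A(c!1).A(q!1)")
        assert (order, rev, kind) == (2, True, "binding")
        assert [(p.mol, p.site) for p in pats] == [("A", "c"), ("A", "q")]

    def test_context_pattern(self):
        _, pats, _, _ = mio.parse_rule_text(
            "trisk(td1,ap!+) + trisk(td2) <-> trisk(td1!1).trisk(td2!1)")
        assert pats[0].context == [("ap", "bound")]
        assert pats[0].site == "td1"

    def test_creation_and_decay(self):
        order, pats, _, kind = mio.parse_rule_text("0 -> A(b)")
        assert (order, kind) == (0, "creation")
        order, pats, _, kind = mio.parse_rule_text("A(b) -> 0")
        assert (order, kind) == (1, "decay")


class TestParsing:
    def test_full_round_trip_all_benchmarks(self, tmp_path):
        """parse(write(model)) reproduces rates, sigma, h, angles to 12
        significant digits for every benchmark system."""
        for name in BENCHMARKS:
            model = build_benchmark(name, scale=0.01)
            d = tmp_path / name
            paths = mio.write_model(model, d)
            re = mio.parse_model(paths["molecules"], paths["reactions"],
                                 paths["config"])
            assert set(re.types) == set(model.types)
            for t in model.type_list:
                t2 = re.types[t.name]
                np.testing.assert_allclose(t2.site_offsets, t.site_offsets,
                                           rtol=1e-12)
                np.testing.assert_allclose(t2.Dt, t.Dt, rtol=1e-12)
            assert len(re.rules) == len(model.rules)
            for r, r2 in zip(model.rules, re.rules):
                for fieldname in ("sigma", "h", "dG_coop", "ka_intrinsic",
                                  "kb_intrinsic", "kon_macro", "koff_macro",
                                  "kclose"):
                    v, v2 = getattr(r, fieldname), getattr(r2, fieldname)
                    if v is None:
                        assert v2 is None
                    else:
                        assert v2 == pytest.approx(v, rel=1e-12), \
                            f"{name}/{r.name}.{fieldname}"

    def test_empty_reaction_file_is_pure_diffusion(self, tmp_path):
        model = build_benchmark("bimol3d", scale=0.005)
        paths = mio.write_model(model, tmp_path)
        paths["reactions"].write_text("")
        re = mio.parse_model(paths["molecules"], paths["reactions"],
                            paths["config"])
        assert re.rules == []
        from prd.serial_engine import Engine
        eng = Engine(re)
        recs = eng.run(5, 5)
        assert recs[-1]["counts"] == recs[0]["counts"]

    def test_unknown_site_error_names_location(self, tmp_path):
        (tmp_path / "A.mol").write_text("name A\nD 10 10 10\nsite b 0 0 0\n")
        (tmp_path / "rx.txt").write_text(
            "reaction A(zz) + A(b) <-> A(zz!1).A(b!1)\nkon 1\nkoff 1\nsigma 1\n")
        (tmp_path / "c.yml").write_text(
            "box: [100,100,100]\ndt: 0.1\ncopies: {A: 2}\n")
        with pytest.raises(mio.ModelParseError, match="zz"):
            mio.parse_model([tmp_path / "A.mol"], tmp_path / "rx.txt",
                            tmp_path / "c.yml")

    def test_conflicting_rate_families_rejected(self, tmp_path):
        (tmp_path / "A.mol").write_text("name A\nD 10 10 10\nsite b 0 0 0\n")
        (tmp_path / "rx.txt").write_text(
            "reaction A(b) + A(b) <-> A(b!1).A(b!1)\n"
            "kon 1\nka 2\nkoff 1\nsigma 1\n")
        (tmp_path / "c.yml").write_text(
            "box: [100,100,100]\ndt: 0.1\ncopies: {A: 2}\n")
        with pytest.raises(mio.ModelParseError, match="both"):
            mio.parse_model([tmp_path / "A.mol"], tmp_path / "rx.txt",
                            tmp_path / "c.yml")

    def test_missing_sigma_rejected(self, tmp_path):
        (tmp_path / "A.mol").write_text("name A\nD 10 10 10\nsite b 0 0 0\n")
        (tmp_path / "rx.txt").write_text(
            "reaction A(b) + A(b) <-> A(b!1).A(b!1)\nkon 1\nkoff 1\n")
        (tmp_path / "c.yml").write_text(
            "box: [100,100,100]\ndt: 0.1\ncopies: {A: 2}\n")
        with pytest.raises(mio.ModelParseError, match="sigma"):
            mio.parse_model([tmp_path / "A.mol"], tmp_path / "rx.txt",
                            tmp_path / "c.yml")

    def test_membrane_flag_required_for_2d(self, tmp_path):
        (tmp_path / "C.mol").write_text(
            "name C\nD 2 2 0\n2D\nsite b 0 0 0\n")
        (tmp_path / "rx.txt").write_text(
            "reaction C(b) + C(b) <-> C(b!1).C(b!1)\nka2d 0.5\nkb2d 15\nsigma 2\n")
        (tmp_path / "c.yml").write_text(
            "box: [100,100,100]\ndt: 0.1\ncopies: {C: 2}\n")
        with pytest.raises(mio.ModelParseError, match="membrane"):
            mio.parse_model([tmp_path / "C.mol"], tmp_path / "rx.txt",
                            tmp_path / "c.yml")


class TestUnits:
    def test_kon_conversion_value(self):
        assert kon3d_to_internal(100.0) == pytest.approx(166.054, abs=1e-3)

    def test_conversion_involutive(self):
        from prd._units import kon3d_to_display, rate1_to_display, \
            rate1_to_internal
        for v in (0.12, 3.22, 100.0):
            assert kon3d_to_display(kon3d_to_internal(v)) == pytest.approx(
                v, rel=1e-15)
            assert rate1_to_display(rate1_to_internal(v)) == pytest.approx(
                v, rel=1e-15)

    @pytest.mark.parametrize("n,box,expect", [
        (10000, (20000, 2000, 2000), 0.2076),
        (6022, (5000, 100, 100), 200.0),
        (0, (5000, 100, 100), 0.0),
    ])
    def test_concentration_from_copies(self, n, box, expect):
        c = copies_to_uM(n, float(np.prod(box)))
        assert c == pytest.approx(expect, abs=2e-4 * max(expect, 1.0))


class TestWriters:
    def test_timeseries_format(self):
        buf = io.StringIO()
        recs = [{"time": 0.0, "counts": {"A": 10000}},
                {"time": 1.0, "counts": {"A": 0}}]
        mio.write_timeseries(recs, buf, 20000 * 2000 * 2000.0)
        lines = buf.getvalue().strip().split("\n")
        assert lines[0].split("\t") == ["time_us", "A_N", "A_uM"]
        assert float(lines[1].split("\t")[2]) == pytest.approx(0.2076,
                                                               abs=1e-4)
        assert float(lines[2].split("\t")[2]) == 0.0

    def test_snapshot_records(self):
        from prd.rigid_body import State
        model = build_benchmark("bimol3d", scale=0.005)
        st = State(model, 4)
        buf = io.StringIO()
        mio.write_snapshot(st, 0.0, buf)
        assert buf.getvalue().splitlines()[0] == "0"
        st.add_molecule(0, [1.0, 2.0, 3.0])
        buf = io.StringIO()
        mio.write_snapshot(st, 1.0, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "2"           # COM + one site
        assert lines[2].startswith("A ")
        assert lines[3].startswith("A.b ")

    def test_restart_round_trip(self, tmp_path):
        import json
        from prd.rigid_body import State
        from prd.serial_engine import Engine
        model = build_benchmark("bimol3d", scale=0.005)
        eng = Engine(model)
        eng.run(5, 5)
        p = tmp_path / "restart.json"
        mio.write_restart(eng.state, p)
        st2 = State.from_dict(model, json.loads(p.read_text()))
        rows = eng.state.live_rows()
        rows2 = st2.live_rows()
        assert np.array_equal(np.sort(eng.state.gid[rows]),
                              np.sort(st2.gid[rows2]))
        np.testing.assert_allclose(
            eng.state.com[rows][np.argsort(eng.state.gid[rows])],
            st2.com[rows2][np.argsort(st2.gid[rows2])], rtol=1e-15)
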