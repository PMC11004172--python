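"""FCS codec: round trips, panel mapping, malformed files, label sidecars."""

import logging
import struct

import numpy as np
import pandas as pd
import pytest

from leukoflow.errors import (
    AlignmentError,
    CapExceeded,
    FormatError,
    PanelMismatch,
    UnknownLabel,
)
from leukoflow.fcs_io import (
    DEFAULT_PANEL,
    ChannelPanel,
    EventMatrix,
    STAIN_NAMES,
    _build_text,
    read_fcs,
    read_label_sidecar,
    write_fcs,
    write_label_sidecar,
)


def _random_em(rng, n=100, sample_id="s"):
    values = rng.uniform(0, 200_000, size=(n, 12))
    return EventMatrix(sample_id, values)


class TestPanel:
    def test_default_panel_is_valid(self):
        assert len(DEFAULT_PANEL.names) == 12
        assert DEFAULT_PANEL.roles.count("fluorescence") == 8
        assert DEFAULT_PANEL.roles.count("scatter") == 4

    @pytest.mark.parametrize(
        "names,roles",
        [
            (("a",) * 12, ("fluorescence",) * 8 + ("scatter",) * 4),  # dup names
            (tuple(f"c{i}" for i in range(11)), ("fluorescence",) * 7 + ("scatter",) * 4),
            (tuple(f"c{i}" for i in range(12)), ("fluorescence",) * 12),  # no scatter
        ],
    )
    def test_invalid_panels_rejected(self, names, roles):
        with pytest.raises(PanelMismatch):
            ChannelPanel(names=names, roles=roles)


class TestEventMatrix:
    def test_cap_exceeded(self):
        with pytest.raises(CapExceeded):
            EventMatrix("big", np.zeros((250_001, 12)))

    def test_configurable_cap(self):
        with pytest.raises(CapExceeded):
            EventMatrix("s", np.zeros((11, 12)), max_events=10)

    def test_non_finite_rejected(self):
        bad = np.zeros((5, 12))
        bad[2, 3] = np.nan
        with pytest.raises(FormatError):
            EventMatrix("s", bad)

    def test_empty_rejected(self):
        with pytest.raises(FormatError):
            EventMatrix("s", np.zeros((0, 12)))


class TestRoundTrip:
    def test_zeros_round_trip(self, tmp_path):
        em = EventMatrix("z", np.zeros((5, 12)))
        path = write_fcs(em, tmp_path / "z.fcs")
        back = read_fcs(path)
        assert back.n_events == 5
        assert np.all(back.values == 0)

    def test_thousand_events(self, tmp_path, rng):
        em = _random_em(rng, n=1000)
        back = read_fcs(write_fcs(em, tmp_path / "k.fcs"))
        assert back.n_events == 1000
        assert back.values.shape == (1000, 12)

    @pytest.mark.parametrize("seed", range(10))
    def test_value_and_order_preserving(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        em = _random_em(rng, n=rng.integers(1, 500))
        back = read_fcs(write_fcs(em, tmp_path / f"r{seed}.fcs"))
        scale = np.maximum(np.abs(em.values), 1.0)
        assert np.max(np.abs(back.values - em.values) / scale) <= 1e-5

    def test_sample_id_from_stem(self, tmp_path, rng):
        path = write_fcs(_random_em(rng), tmp_path / "patient42.fcs")
        assert read_fcs(path).sample_id == "patient42"


def _write_custom_fcs(path, values, pnn, pns):
    """Hand-rolled FCS writer for fixtures with arbitrary parameter names."""
    n, p = values.shape
    data = values.astype("<f4").tobytes()
    kw = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BEGINDATA": "0" * 10, "$ENDDATA": "0" * 10,
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0", "$PAR": str(p), "$TOT": str(n),
    }
    for i in range(p):
        kw[f"$P{i + 1}B"] = "32"
        kw[f"$P{i + 1}E"] = "0,0"
        kw[f"$P{i + 1}N"] = pnn[i]
        kw[f"$P{i + 1}S"] = pns[i]
        kw[f"$P{i + 1}R"] = "262144"
    text = _build_text(kw)
    ts, te = 58, 58 + len(text) - 1
    ds, de = te + 1, te + len(data)
    kw["$BEGINDATA"] = str(ds).rjust(10, "0")
    kw["$ENDDATA"] = str(de).rjust(10, "0")
    text = _build_text(kw)
    header = (
        b"FCS3.1    " + f"{ts:>8d}{te:>8d}{ds:>8d}{de:>8d}{0:>8d}{0:>8d}".encode()
    )
    path.write_bytes(header + text + data)
    return path


class TestReadEdgeCases:
    def test_extra_time_parameter_ignored_with_warning(self, tmp_path, rng, caplog):
        values12 = rng.uniform(0, 1000, (50, 12))
        values = np.column_stack([values12, np.arange(50.0)])  # Time column
        pnn = list(DEFAULT_PANEL.names) + ["Time"]
        pns = [STAIN_NAMES[c] for c in DEFAULT_PANEL.names] + ["Time"]
        path = _write_custom_fcs(tmp_path / "t.fcs", values, pnn, pns)
        with caplog.at_level(logging.WARNING):
            em = read_fcs(path)
        assert em.values.shape == (50, 12)
        assert any("extra" in r.message.lower() for r in caplog.records)
        np.testing.assert_allclose(em.values, values12, rtol=1e-5)

    def test_header_offset_disagreement_raises(self, tmp_path, rng):
        path = write_fcs(_random_em(rng), tmp_path / "c.fcs")
        raw = bytearray(path.read_bytes())
        raw[26:34] = f"{999:>8d}".encode()  # corrupt header DATA-start field
        path.write_bytes(bytes(raw))
        with pytest.raises(FormatError):
            read_fcs(path)

    def test_nan_in_data_raises(self, tmp_path, rng):
        path = write_fcs(_random_em(rng, n=10), tmp_path / "n.fcs")
        raw = bytearray(path.read_bytes())
        raw[-4:] = struct.pack("<f", np.nan)
        path.write_bytes(bytes(raw))
        with pytest.raises(FormatError):
            read_fcs(path)

    def test_missing_panel_channel_raises(self, tmp_path, rng):
        values = rng.uniform(0, 1000, (20, 12))
        pnn = [f"P{i}" for i in range(12)]  # anonymous names, no CD markers
        path = _write_custom_fcs(tmp_path / "m.fcs", values, pnn, pnn)
        with pytest.raises(PanelMismatch):
            read_fcs(path)

    def test_wrong_version_rejected(self, tmp_path):
        path = tmp_path / "v.fcs"
        path.write_bytes(b"FCS2.0    " + b" " * 48)
        with pytest.raises(FormatError):
            read_fcs(path)

    def test_vendor_stain_name_variants_map(self, tmp_path, rng):
        values = rng.uniform(0, 1000, (20, 12))
        pns = [
            "cyCD3 Pacific Blue", "CD45 KrO", "MPO FITC", "CyCD79a PE",
            "CD34 PerCP-Cy5.5", "CD19 PC7", "CD7 APC", "smCD3 APC-H7",
            "FSC-A", "FSC-H", "SSC-A", "SSC-H",
        ]
        pnn = [f"FL{i}" for i in range(8)] + ["FSC-A", "FSC-H", "SSC-A", "SSC-H"]
        path = _write_custom_fcs(tmp_path / "v2.fcs", values, pnn, pns)
        em = read_fcs(path)
        np.testing.assert_allclose(em.values, values, rtol=1e-5)


class TestLabelSidecar:
    def test_constant_labels_round_trip(self, tmp_path):
        labels = np.full(30, "Neu")
        path = write_label_sidecar(labels, tmp_path / "l.csv")
        back = read_label_sidecar(path, 30)
        assert (back == "Neu").all()

    def test_missing_rows_default_to_debris(self, tmp_path):
        df = pd.DataFrame(
            {"event_index": [i for i in range(30) if not 10 <= i <= 20],
             "label": "T-lym"}
        )
        path = tmp_path / "gap.csv"
        df.to_csv(path, index=False)
        back = read_label_sidecar(path, 30)
        assert (back[10:21] == "debris").all()
        assert (back[:10] == "T-lym").all()

    def test_unknown_label_rejected(self, tmp_path):
        # basophils cannot be identified in the ALOT panel: not a valid class
        path = tmp_path / "u.csv"
        pd.DataFrame({"event_index": [0], "label": ["Basophil"]}).to_csv(
            path, index=False
        )
        with pytest.raises(UnknownLabel):
            read_label_sidecar(path, 5)

    def test_out_of_range_index_rejected(self, tmp_path):
        path = tmp_path / "o.csv"
        pd.DataFrame({"event_index": [99], "label": ["Neu"]}).to_csv(path, index=False)
        with pytest.raises(AlignmentError):
            read_label_sidecar(path, 10)
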