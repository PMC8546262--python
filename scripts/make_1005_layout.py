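"""Generate the canonical 10/5 electrode table packaged with lesioncond.

Builds unit-sphere directions for a 128-channel high-density EEG layout
(10/5 naming) plus a nasion reference, using the classical proportional-arc
construction on an ideal sphere:

* head frame: x right, y anterior, z superior; Cz at (0, 0, 1);
* the midline arc nasion -> Cz -> inion is divided in 10 % steps;
* the circumferential ring (Fpz, Fp1/2, AF7/8, ..., Oz) sits at 72 deg
  polar angle and is divided into 20 equal azimuthal segments;
* a lower ring (9/10- and I-labelled positions, and the nasion) sits on the
  equator with the same azimuth scheme;
* interior electrodes lie on great-circle arcs from the midline to the ring
  at proportional fractions (10 % columns; 5 % "h" columns).

Writes ``src/lesioncond/data/layout_1005.tsv`` (label, x, y, z).
"""

from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src" / "lesioncond" / "data" / "layout_1005.tsv"

RING_POLAR = 72.0  # deg from Cz


def sph(polar_deg, az_deg):
    t = np.radians(polar_deg)
    p = np.radians(az_deg)
    return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def slerp(u, w, t):
    u = u / np.linalg.norm(u)
    w = w / np.linalg.norm(w)
    ang = np.arccos(np.clip(u @ w, -1.0, 1.0))
    if ang < 1e-12:
        return u
    return (np.sin((1 - t) * ang) * u + np.sin(t * ang) * w) / np.sin(ang)


def build_table():
    pos = {}

    # midline (anterior az 90, posterior az 270)
    pos["Cz"] = sph(0, 0)
    for lab, polar, az in [
        ("AFz", 54, 90), ("Fz", 36, 90), ("FCz", 18, 90),
        ("CPz", 18, 270), ("Pz", 36, 270), ("POz", 54, 270),
    ]:
        pos[lab] = sph(polar, az)

    # circumferential ring, 18 deg azimuth steps starting at Fpz (az 90)
    ring = {
        "Fpz": 90, "Fp1": 108, "AF7": 126, "F7": 144, "FT7": 162, "T7": 180,
        "TP7": 198, "P7": 216, "PO7": 234, "O1": 252, "Oz": 270, "O2": 288,
        "PO8": 306, "P8": 324, "TP8": 342, "T8": 0, "FT8": 18, "F8": 36,
        "AF8": 54, "Fp2": 72,
        # intermediate-row ring positions (h rows)
        "AFF7h": 135, "FFT7h": 153, "FTT7h": 171, "TTP7h": 189, "TPP7h": 207,
        "PPO7h": 225, "POO9h": 243,
        "AFF8h": 45, "FFT8h": 27, "FTT8h": 9, "TTP8h": 351, "TPP8h": 333,
        "PPO8h": 315, "POO10h": 297,
    }
    for lab, az in ring.items():
        pos[lab] = sph(RING_POLAR, az)

    # lower (equator) ring: 9/10- and I-labelled positions + nasion
    lower = {
        "F9": 144, "FT9": 162, "FTT9h": 171, "TP9": 198, "TPP9h": 207,
        "P9": 216, "PO9": 234, "I1": 252, "Iz": 270, "I2": 288, "PO10": 306,
        "P10": 324, "TPP10h": 333, "TP10": 342, "FTT10h": 9, "FT10": 18,
        "F10": 36,
    }
    for lab, az in lower.items():
        pos[lab] = sph(90.0, az)
    nasion = sph(90.0, 90.0)

    # interior rows: (midline polar, anterior?, left ring label, right ring
    # label, column names with arc fractions from midline)
    cols_10 = [("1", "2", 0.25), ("3", "4", 0.50), ("5", "6", 0.75)]
    cols_05 = [("1h", "2h", 0.125), ("3h", "4h", 0.375), ("5h", "6h", 0.625)]
    rows = [
        ("AF", 54, 90, "AF7", "AF8", [("3", "4", 0.50)]),
        ("AFF", 45, 90, "AFF7h", "AFF8h", [("1", "2", 0.25), ("5h", "6h", 0.625)]),
        ("F", 36, 90, "F7", "F8", cols_10),
        ("FFC", 27, 90, "FFT7h", "FFT8h", cols_05),
        ("FC", 18, 90, "FT7", "FT8", cols_10),
        ("FCC", 9, 90, "FTT7h", "FTT8h", cols_05),
        ("C", 0, 90, "T7", "T8", cols_10),
        ("CCP", 9, 270, "TTP7h", "TTP8h", cols_05),
        ("CP", 18, 270, "TP7", "TP8", cols_10),
        ("CPP", 27, 270, "TPP7h", "TPP8h", cols_05),
        ("P", 36, 270, "P7", "P8", cols_10),
        ("PPO", 45, 270, "PPO7h", "PPO8h", [("1h", "2h", 0.125), ("5h", "6h", 0.625)]),
        ("PO", 54, 270, "PO7", "PO8", [("3", "4", 0.50)]),
        ("AFp", 63, 90, "Fp1", "Fp2", [("1", "2", 0.25)]),
        ("POO", 63, 270, "POO9h", "POO10h", [("1", "2", 0.25)]),
    ]
    for name, polar, az, left, right, cols in rows:
        mid = sph(polar, az)
        for cl, cr, t in cols:
            pos[name + cl] = slerp(mid, pos[left], t)
            pos[name + cr] = slerp(mid, pos[right], t)

    assert len(pos) == 128, f"expected 128 measurement labels, got {len(pos)}"
    required = {
        "Fp1", "Fp2", "F7", "F8", "FT9", "FT10", "FTT9h", "FTT10h", "T7", "T8",
        "TTP7h", "TTP8h", "TP7", "TP8", "TPP9h", "TPP10h", "P9", "P10", "I1",
        "I2", "Cz", "FCz", "CPz", "C1", "C2", "FFC1h", "Fz", "AFF1",
    }
    missing = required - set(pos)
    assert not missing, f"missing required labels: {missing}"
    pos["nasion"] = nasion
    return pos


def main():
    pos = build_table()
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w") as fh:
        fh.write("label\tx\ty\tz\n")
        for lab, p in pos.items():
            fh.write(f"{lab}\t{p[0]:.8f}\t{p[1]:.8f}\t{p[2]:.8f}\n")
    print(f"wrote {OUT} ({len(pos)} rows)")


if __name__ == "__main__":
    main()
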