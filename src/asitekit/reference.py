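"""Reference solution-thermodynamics measurements for the A-site models.

Measured duplex-formation parameters (UV melting and ITC, 21 degC, 10 mM
phosphate / 20 mM NaCl) for the prokaryotic and eukaryotic decoding A-site
constructs (strand A + strand B) and for the duplexes of the three
2'-O-methyl oligomers with prokaryotic strand B.  These tables serve as
simulation conditions for the synthetic generators and as consistency
surfaces (dG = dH - TdS = -R T ln Ka at 294.15 K).

Units: dH, TdS, dG in kcal/mol; Tm in degC; Ka in 1/M; values in the
``se`` dicts are the reported standard errors.
"""

from __future__ import annotations

#: UV melting (c0 = 2 uM per strand), two-state fits with sloping baselines.
MELT_UV: dict[str, dict[str, float]] = {
    "prokaryotic": {"dH": -99.8, "TdS": -81.5, "dG": -18.3, "Tm": 52.9},
    "eukaryotic": {"dH": -90.2, "TdS": -76.1, "dG": -14.1, "Tm": 42.6},
    "1489": {"dH": -72.9, "TdS": -58.5, "dG": -14.4, "Tm": 47.4},
    "1490": {"dH": -68.7, "TdS": -54.8, "dG": -13.9, "Tm": 46.1},
    "1491": {"dH": -73.0, "TdS": -59.7, "dG": -13.3, "Tm": 42.1},
}

MELT_UV_SE: dict[str, dict[str, float]] = {
    "prokaryotic": {"dH": 0.9, "TdS": 0.9, "dG": 1.8, "Tm": 0.5},
    "eukaryotic": {"dH": 0.7, "TdS": 0.8, "dG": 1.5, "Tm": 0.5},
    "1489": {"dH": 0.9, "TdS": 0.6, "dG": 1.5, "Tm": 0.5},
    "1490": {"dH": 0.7, "TdS": 0.6, "dG": 1.3, "Tm": 0.5},
    "1491": {"dH": 0.8, "TdS": 0.6, "dG": 1.4, "Tm": 0.5},
}

#: ITC 1:1 fits (A-site models: 20 x 2 uL of 100 uM strand A into 10 uM
#: strand B; oligomer duplexes: 25 x 2 uL of 70 uM oligomer into 10 uM
#: prokaryotic strand B).
ITC: dict[str, dict[str, float]] = {
    "prokaryotic": {"dH": -115.1, "TdS": -105.1, "dG": -10.0, "Ka": 2.4e7, "n": 0.89},
    "eukaryotic": {"dH": -76.0, "TdS": -66.5, "dG": -9.5, "Ka": 1.1e7, "n": 0.85},
    "1489": {"dH": -40.6, "TdS": -30.8, "dG": -9.8, "Ka": 1.9e7, "n": 0.91},
    "1490": {"dH": -37.8, "TdS": -28.3, "dG": -9.5, "Ka": 1.2e7, "n": 0.93},
    "1491": {"dH": -43.2, "TdS": -34.3, "dG": -8.9, "Ka": 0.5e7, "n": 1.01},
}

ITC_SE: dict[str, dict[str, float]] = {
    "prokaryotic": {"dH": 3.7, "TdS": 4.3, "dG": 0.5, "Ka": 1.1e7, "n": 0.02},
    "eukaryotic": {"dH": 1.8, "TdS": 2.1, "dG": 0.4, "Ka": 0.2e7, "n": 0.02},
    "1489": {"dH": 2.5, "TdS": 1.5, "dG": 0.5, "Ka": 1.5e7, "n": 0.02},
    "1490": {"dH": 2.1, "TdS": 1.4, "dG": 0.5, "Ka": 0.7e7, "n": 0.02},
    "1491": {"dH": 1.1, "TdS": 1.5, "dG": 0.4, "Ka": 0.1e7, "n": 0.02},
}

#: ITC injection schemes per system key.
ITC_SCHEME: dict[str, dict[str, float | int]] = {
    "model": {"n_inj": 20, "inj_volume": 2e-6, "syringe_conc": 100e-6,
              "cell_conc": 10e-6},
    "oligomer": {"n_inj": 25, "inj_volume": 2e-6, "syringe_conc": 70e-6,
                 "cell_conc": 10e-6},
}


def scheme_for(system: str) -> dict[str, float | int]:
    return ITC_SCHEME["model" if system in ("prokaryotic", "eukaryotic")
                      else "oligomer"]
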