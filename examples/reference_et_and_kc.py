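"""Ground-truth arm: reference ET, crop-coefficient curve, atmometer ETa.

Computes standardized tall-crop (alfalfa) reference ET for a synthetic summer
day, walks the default corn Kc curve (emergence to maturity, peak at
effective cover 55 days after emergence), and converts reference ET to actual
crop ET by ETa = ETr x Kc — the estimate the energy-balance maps are
validated against.
"""

from metricet import reference_kc as rk

ta, u2, rn_mj, elev = 25.0, 2.0, 15.0, 500.0
ea = float(rk.saturation_vapor_pressure(ta)) - 1.5  # 1.5 kPa vapor deficit
etr = rk.asce_pm_etr(ta, u2, ea, rn_mj, elevation=elev)
print(f"daily alfalfa-reference ETr at {ta:.0f} C, u2={u2:.0f} m/s: {etr:.2f} mm/day")

curve = rk.KcCurve(emergence_doy=140)
for doy, stage in [(140, "emergence"), (168, "rising limb"),
                   (195, "effective cover"), (250, "late season")]:
    kc = rk.kc_at(curve, doy)
    print(f"DOY {doy} ({stage:15s}): Kc = {kc:.3f}, ETa = {rk.atmometer_eta(etr, kc):.2f} mm/day")
print("ETa follows the Kc curve: ~25% of reference at emergence, equal to")
print("reference at full cover, declining as the crop matures.")
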