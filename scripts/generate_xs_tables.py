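"""One-time generator for the embedded cross-section and form-factor tables.

Run in the build sandbox (requires xraylib); outputs static CSVs under
src/cbctmc/data/. The shipped package never imports xraylib.
"""
import numpy as np
import xraylib as xl

MATERIALS = {
    # name -> (formula or NIST compound, rho_nominal)
    "Vacuum": (None, 0.0),
    "Air": ("Air, Dry (near sea level)", 1.205e-3),
    "PMP": ("C6H12", 0.83),
    "LDPE": ("C2H4", 0.93),
    "Polystyrene": ("C8H8", 1.06),
    "Water": ("H2O", 1.00),
    "Acrylic": ("C5H8O2", 1.19),
    "Delrin": ("CH2O", 1.41),
    "Teflon": ("C2F4", 2.10),
}

AIR_COMP = {7: 0.755268, 8: 0.231781, 18: 0.012827, 6: 0.000124}  # mass fractions


def elements_of(formula):
    if formula == "Air, Dry (near sea level)":
        return AIR_COMP
    cd = xl.CompoundParser(formula)
    return {z: w for z, w in zip(cd["Elements"], cd["massFractions"])}


energies = np.arange(10.0, 151.0, 1.0)
with open("src/cbctmc/data/xs_tables.csv", "w") as f:
    f.write("material,energy_kev,total_cm2_g,photo_cm2_g,incoh_cm2_g,coh_cm2_g\n")
    for name, (formula, rho) in MATERIALS.items():
        for e in energies:
            if formula is None:
                pe = inc = coh = 0.0
            else:
                pe = xl.CS_Photo_CP(formula, e)
                inc = xl.CS_Compt_CP(formula, e)
                coh = xl.CS_Rayl_CP(formula, e)
            tot = pe + inc + coh
            f.write(f"{name},{e:.1f},{tot:.6e},{pe:.6e},{inc:.6e},{coh:.6e}\n")

# Rayleigh squared form factors, independent-atom sum, vs momentum transfer x
# = sin(theta/2)/lambda in 1/Angstrom.  F2 normalised per gram-atom mixture:
# F2(x) = sum_i (w_i / A_i) * F_i(x)^2   [per-atom weighting by number]
xgrid = np.concatenate([np.arange(0, 2.0, 0.02), np.arange(2.0, 12.01, 0.1)])
with open("src/cbctmc/data/rayleigh_ff.csv", "w") as f:
    f.write("material,x_invA,f2\n")
    for name, (formula, rho) in MATERIALS.items():
        if formula is None:
            continue
        comp = elements_of(formula)
        for x in xgrid:
            f2 = sum(
                (w / xl.AtomicWeight(z)) * xl.FF_Rayl(z, float(x)) ** 2
                for z, w in comp.items()
            )
            f.write(f"{name},{x:.3f},{f2:.6e}\n")

# electrons per gram for each material (Z/A weighted), used for KN sampling docs
for name, (formula, rho) in MATERIALS.items():
    if formula is None:
        print(name, 0.0)
        continue
    comp = elements_of(formula)
    ne = sum(w * z / xl.AtomicWeight(z) for z, w in comp.items()) * 6.02214076e23
    print(name, f"{ne:.6e}")
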