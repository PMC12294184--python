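"""Render one tooth-bud phantom and recover its parameters.

Builds a noiseless phantom crown with known enamel angle (EA), dentine
angle (DA) and enamel/dentine grey levels, then runs the full measurement
chain — reference rectangle, angle tools, densitometry profile — on the
ground-truth landmarks.  Measured values should match the generating spec
to rasterization precision.
"""

from enamelmetrics import PhantomSpec, generate_phantom, measure_tooth

spec = PhantomSpec(
    crown_width_px=160,
    crown_height_px=120,
    enamel_thickness_px=18.0,
    ea_true_deg=15.0,      # enamel surface, degrees off the rectangle side
    da_true_deg=7.0,       # dentine-enamel junction
    enamel_grey=140.0,
    dentine_grey=120.0,    # true EDMR = 140/120 = 1.1667
)
phantom = generate_phantom(spec)
result = measure_tooth(phantom.pixels, phantom.truth_landmarks)

print(f"image: {phantom.shape[1]} x {phantom.shape[0]} px, {phantom.pixels.dtype}")
print(f"{'parameter':<10}{'truth':>10}{'measured (mesial/distal)':>30}")
print(f"{'W (px)':<10}{spec.crown_width_px:>10}{result['w_px']:>30.2f}")
print(f"{'H (px)':<10}{spec.crown_height_px:>10}{result['h_px']:>30.2f}")
for name, truth in (("EA (deg)", spec.ea_true_deg), ("DA (deg)", spec.da_true_deg),
                    ("EDMR", spec.edmr_true)):
    key = {"EA (deg)": "ea_deg", "DA (deg)": "da_deg", "EDMR": "edmr"}[name]
    pair = f"{result[f'{key}_mesial']:.4f} / {result[f'{key}_distal']:.4f}"
    print(f"{name:<10}{truth:>10.4f}{pair:>30}")

# The EDMR is the mean grey of the middle third of the enamel half of a
# profile line divided by that of the dentine half; on a noiseless phantom
# it reproduces enamel_grey / dentine_grey up to 8-bit quantization.
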