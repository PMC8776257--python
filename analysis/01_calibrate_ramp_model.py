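"""Calibrate the linear CA3->CA1 ramp model and write the reference field.

Finds the voltage scale c and the Gaussian weight-profile width for which
synaptic weights spanning 1-2.5 produce the reference place field (6 mV
peak, 108 cm width) on the 185 cm track, then writes the calibrated
constants and the reference ramp to results/.
"""

import json
import os

import numpy as np

from btspsim.ramp import (calibrate_scaling, gaussian_weight_profile,
                          make_input_population, ramp_from_weights,
                          ramp_width)

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    pop = make_input_population()
    c, sigma_w = calibrate_scaling(pop)
    w = gaussian_weight_profile(pop, pop.track_length / 2, sigma_w)
    ramp = ramp_from_weights(w, pop, c)
    print(f"input population: {pop.n_inputs} fields, sigma={pop.sigma} cm, "
          f"spacing {pop.spacing:.3f} cm")
    print(f"calibrated scale c = {c:.6g} mV per weighted Hz; "
          f"weight-profile width sigma_w = {sigma_w:.2f} cm")
    print(f"reference ramp: amplitude {ramp.amplitude:.3f} mV, "
          f"width {ramp_width(ramp):.2f} cm")

    with open(os.path.join(OUT, "ramp_calibration.json"), "w") as fh:
        json.dump({"c": c, "sigma_w": sigma_w,
                   "amplitude_mv": ramp.amplitude,
                   "width_cm": ramp_width(ramp)}, fh, indent=2)
    header = "bin_center_cm,weight_profile,ramp_mv"
    table = np.column_stack([ramp.bin_centers,
                             np.interp(ramp.bin_centers,
                                       pop.peak_locations, w),
                             ramp.values])
    np.savetxt(os.path.join(OUT, "reference_ramp.csv"), table,
               delimiter=",", header=header, comments="")
    print(f"wrote {OUT}/ramp_calibration.json and reference_ramp.csv")


if __name__ == "__main__":
    main()
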