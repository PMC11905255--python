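"""Canonical experiment configurations.

These encode the study conditions of the synthetic QA experiments: a
desk-scale single-field verification twin (50^3 voxels at 2 mm, three
orthogonal parallel-view cameras, mild Poisson noise, 5% scattered-light
fraction) and a three-field IMRT delivery (beams at 270/230/310 degrees,
one frame per second).  Field shapes, penumbra width and depth attenuation
are documented defaults chosen to resemble a 6 MV linac beam; the rationale
lives in the methods documentation.
"""

from __future__ import annotations

from .config import RunConfig

__all__ = ["single_field_qa_config", "imrt_three_field_config"]


def _cameras(n_pix: int, pitch: float, lam: float = 0.002) -> list[dict]:
    return [
        {"id": "cam_top", "view_axis": "+z", "pixel_shape": (n_pix, n_pix),
         "pixel_pitch_mm": pitch, "attenuation_lambda_per_mm": lam},
        {"id": "cam_front", "view_axis": "-y", "pixel_shape": (n_pix, n_pix),
         "pixel_pitch_mm": pitch, "attenuation_lambda_per_mm": lam},
        {"id": "cam_side", "view_axis": "+x", "pixel_shape": (n_pix, n_pix),
         "pixel_pitch_mm": pitch, "attenuation_lambda_per_mm": lam},
    ]


def single_field_qa_config(seed: int = 1) -> RunConfig:
    """Scaled-down single-field QA twin.

    A 60 x 60 mm square field irradiated vertically onto a 10 cm scintillator
    cube discretized at 2 mm (50^3 voxels), imaged by three orthogonal
    cameras whose sensors extend 10 mm beyond the phantom on each side (the
    margin pixels feed the scattered-light estimate).  The 80 x 80 mm
    reference field drives both the weighted-dose-integral calibration and
    the final dose-scale calibration over the central 5 x 5 cm region.
    """
    return RunConfig.model_validate({
        "grid": {"shape": (50, 50, 50), "voxel_size_mm": 2.0},
        "beams": [{
            "gantry_angle_deg": 270.0,
            "field_size_mm": (60.0, 60.0),
            "penumbra_sigma_mm": 3.0,
            "attenuation_mu_per_mm": 0.005,
            "weight": 1.0,
            "duration_s": 1.0,
        }],
        "cameras": _cameras(n_pix=60, pitch=2.0),
        "noise": {"poisson_gain": 1e4, "read_sigma": 0.0},
        "reference": {"field_size_mm": (80.0, 80.0), "penumbra_sigma_mm": 3.0,
                      "attenuation_mu_per_mm": 0.005},
        "calibration": {"region_width_mm": 50.0, "region_height_mm": 50.0,
                        "axis": "z", "coordinate_mm": 0.0},
        "scatter_fraction": 0.05,
        "solver": {"max_iters": 600, "tol": 1e-9},
        "frame_rate_hz": 1.0,
        "seed": seed,
    })


def imrt_three_field_config(seed: int = 1) -> RunConfig:
    """Three-field IMRT delivery at 270/230/310 degrees, 2 mm resolution.

    Each subfield is delivered for one second at one frame per second, so
    the time-resolved path reconstructs one increment per subfield.
    """
    return RunConfig.model_validate({
        "grid": {"shape": (50, 50, 50), "voxel_size_mm": 2.0},
        "beams": [
            {"gantry_angle_deg": 270.0, "field_size_mm": (40.0, 40.0),
             "penumbra_sigma_mm": 3.0, "attenuation_mu_per_mm": 0.005,
             "weight": 1.0, "duration_s": 1.0},
            {"gantry_angle_deg": 230.0, "field_size_mm": (40.0, 40.0),
             "penumbra_sigma_mm": 3.0, "attenuation_mu_per_mm": 0.005,
             "weight": 1.0, "duration_s": 1.0},
            {"gantry_angle_deg": 310.0, "field_size_mm": (40.0, 40.0),
             "penumbra_sigma_mm": 3.0, "attenuation_mu_per_mm": 0.005,
             "weight": 1.0, "duration_s": 1.0},
        ],
        "cameras": _cameras(n_pix=60, pitch=2.0),
        "noise": {"poisson_gain": 1e4, "read_sigma": 0.0},
        "reference": {"field_size_mm": (80.0, 80.0), "penumbra_sigma_mm": 3.0,
                      "attenuation_mu_per_mm": 0.005},
        "scatter_fraction": 0.05,
        "solver": {"max_iters": 600, "tol": 1e-9},
        "frame_rate_hz": 1.0,
        "seed": seed,
    })
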