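{
  "version": 1,
  "comment": "Per-(group, class) calibration targets for the zero-inflated truncated log-normal rate models. 'mean', 'median', and 'range_max' are events/ml summary statistics of the emulated study population; 'detect_fraction' is the share of samples at or above 'detect_threshold' events/ml (null where unreported, in which case the zero-inflation weight falls back to documented defaults). Entries for dp.CTC, hem.cell, vim.hem.cell, and dapi.only have no published per-group statistics and use one group-invariant, package-chosen profile so these classes carry no group signal.",
  "targets": [
    {"label": "epi.CTC", "group": "late", "mean": 6.75, "median": 2.02, "range_max": 50.10, "detect_fraction": 0.75, "detect_threshold": 0.0},
    {"label": "epi.CTC", "group": "early", "mean": 0.77, "median": 0.0, "range_max": 12.13, "detect_fraction": 0.27, "detect_threshold": 0.0},
    {"label": "epi.CTC", "group": "normal", "mean": 0.39, "median": 0.0, "range_max": 2.0, "detect_fraction": null, "detect_threshold": 0.0},

    {"label": "mes.CTC", "group": "late", "mean": 2.52, "median": 1.02, "range_max": 16.42, "detect_fraction": null, "detect_threshold": 0.0},
    {"label": "mes.CTC", "group": "early", "mean": 0.91, "median": 0.0, "range_max": 7.06, "detect_fraction": null, "detect_threshold": 0.0},
    {"label": "mes.CTC", "group": "normal", "mean": 0.55, "median": 0.0, "range_max": 5.0, "detect_fraction": null, "detect_threshold": 0.0},

    {"label": "tp.CTC", "group": "late", "mean": 4.34, "median": 2.07, "range_max": 40.56, "detect_fraction": null, "detect_threshold": 0.0},
    {"label": "tp.CTC", "group": "early", "mean": 12.80, "median": 1.80, "range_max": 240.04, "detect_fraction": null, "detect_threshold": 0.0},
    {"label": "tp.CTC", "group": "normal", "mean": 1.56, "median": 0.0, "range_max": 17.062, "detect_fraction": null, "detect_threshold": 0.0},

    {"label": "vim.cell", "group": "late", "mean": 14.43, "median": 4.74, "range_max": 266.82, "detect_fraction": null, "detect_threshold": 0.0},
    {"label": "vim.cell", "group": "early", "mean": 3.84, "median": 1.44, "range_max": 27.81, "detect_fraction": null, "detect_threshold": 0.0},
    {"label": "vim.cell", "group": "normal", "mean": 1.72, "median": 0.93, "range_max": 12.10, "detect_fraction": null, "detect_threshold": 0.0},

    {"label": "LEV", "group": "early", "mean": 43.78, "median": 20.31, "range_max": 400.52, "detect_fraction": 0.94, "detect_threshold": 1.0},
    {"label": "LEV", "group": "late", "mean": 2.92, "median": 1.37, "range_max": 21.91, "detect_fraction": 0.60, "detect_threshold": 1.0},
    {"label": "LEV", "group": "normal", "mean": 0.99, "median": 0.0, "range_max": 6.73, "detect_fraction": null, "detect_threshold": 1.0},

    {"label": "dp.CTC", "group": "late", "mean": 1.2, "median": 0.0, "range_max": 15.0, "detect_fraction": null, "detect_threshold": 0.0},
    {"label": "dp.CTC", "group": "early", "mean": 1.2, "median": 0.0, "range_max": 15.0, "detect_fraction": null, "detect_threshold": 0.0},
    {"label": "dp.CTC", "group": "normal", "mean": 1.2, "median": 0.0, "range_max": 15.0, "detect_fraction": null, "detect_threshold": 0.0},

    {"label": "hem.cell", "group": "late", "mean": 2.5, "median": 1.0, "range_max": 20.0, "detect_fraction": null, "detect_threshold": 0.0},
    {"label": "hem.cell", "group": "early", "mean": 2.5, "median": 1.0, "range_max": 20.0, "detect_fraction": null, "detect_threshold": 0.0},
    {"label": "hem.cell", "group": "normal", "mean": 2.5, "median": 1.0, "range_max": 20.0, "detect_fraction": null, "detect_threshold": 0.0},

    {"label": "vim.hem.cell", "group": "late", "mean": 1.0, "median": 0.0, "range_max": 12.0, "detect_fraction": null, "detect_threshold": 0.0},
    {"label": "vim.hem.cell", "group": "early", "mean": 1.0, "median": 0.0, "range_max": 12.0, "detect_fraction": null, "detect_threshold": 0.0},
    {"label": "vim.hem.cell", "group": "normal", "mean": 1.0, "median": 0.0, "range_max": 12.0, "detect_fraction": null, "detect_threshold": 0.0},

    {"label": "dapi.only", "group": "late", "mean": 3.0, "median": 1.2, "range_max": 30.0, "detect_fraction": null, "detect_threshold": 0.0},
    {"label": "dapi.only", "group": "early", "mean": 3.0, "median": 1.2, "range_max": 30.0, "detect_fraction": null, "detect_threshold": 0.0},
    {"label": "dapi.only", "group": "normal", "mean": 3.0, "median": 1.2, "range_max": 30.0, "detect_fraction": null, "detect_threshold": 0.0}
  ]
}
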