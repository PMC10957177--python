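{
  "coactivated": {
    "contrasts": [
      "KET_vs_saline",
      "ISO_vs_homecage"
    ],
    "count": 6,
    "per_division": {},
    "regions": [
      "R15",
      "R16",
      "R17",
      "R18",
      "R19",
      "R20"
    ]
  },
  "contrasts": {
    "ISO_vs_homecage": {
      "cluster_k": 5,
      "cluster_mean_z": {
        "1": 10.96706289,
        "2": -0.0569388088,
        "3": 1.352673482,
        "4": -0.1250731238,
        "5": -0.4728744013
      },
      "mean_silhouette": 0.2206673938,
      "n_regions_tested": 53,
      "n_selected": 4,
      "n_significant": 8,
      "selected": [
        "R20",
        "R24",
        "R18",
        "R19"
      ]
    },
    "KET_vs_saline": {
      "cluster_k": 2,
      "cluster_mean_z": {
        "1": 10.6748031,
        "2": -0.8032543492
      },
      "mean_silhouette": 0.6410449462,
      "n_regions_tested": 53,
      "n_selected": 8,
      "n_significant": 20,
      "selected": [
        "R19",
        "R14",
        "R12",
        "R03",
        "R08",
        "R17",
        "R06",
        "R05"
      ]
    }
  },
  "ground_truth_file": "ground_truth.json",
  "networks": {
    "ISO": {
      "density": 0.05079825835,
      "hubs": [
        "R35",
        "R37",
        "R46"
      ],
      "n_edges": 70,
      "n_modules": 6,
      "n_nodes": 53
    },
    "KET": {
      "density": 0.0297532656,
      "hubs": [
        "R01",
        "R13",
        "R30",
        "R32",
        "R35",
        "R37",
        "R49"
      ],
      "n_edges": 41,
      "n_modules": 6,
      "n_nodes": 53
    },
    "homecage": {
      "density": 0.04571843251,
      "hubs": [
        "R31",
        "R32",
        "R33",
        "R40",
        "R42",
        "R46"
      ],
      "n_edges": 63,
      "n_modules": 6,
      "n_nodes": 53
    },
    "saline": {
      "density": 0.03410740203,
      "hubs": [
        "R36",
        "R41",
        "R46"
      ],
      "n_edges": 47,
      "n_modules": 6,
      "n_nodes": 53
    }
  },
  "parameters": {
    "alpha": 0.05,
    "cluster_cut": 0.5,
    "effect_fraction": 0.4,
    "hub_quantile": 0.8,
    "level": null,
    "method": "zmean",
    "module_cut": 0.7,
    "q": 0.05,
    "r_min": 0.82,
    "seed": 1
  },
  "schema_version": 1
}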