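{
  "_description": "Published benchmark confusion matrices (rows = true class, columns = predicted class) for fine-tuned CNN classifiers on IMU activity-image datasets, in the initial (converted images only) and enhanced (9x augmented) states. Used as fixed inputs to validate the macro-averaged metric computation.",
  "uci_har_resnet50": {
    "classes": ["walking", "ascent", "descent", "sitting", "standing", "laying"],
    "initial": [
      [106, 0, 0, 0, 0, 0],
      [0, 108, 0, 0, 0, 0],
      [0, 1, 106, 0, 0, 0],
      [0, 0, 0, 89, 3, 12],
      [1, 1, 0, 14, 66, 11],
      [0, 0, 0, 2, 4, 76]
    ],
    "enhanced": [
      [494, 0, 1, 0, 0, 0],
      [1, 547, 3, 0, 0, 0],
      [1, 0, 477, 0, 0, 0],
      [0, 0, 1, 465, 12, 17],
      [0, 0, 0, 19, 461, 11],
      [0, 0, 0, 15, 8, 467]
    ]
  },
  "wisdm_resnet18": {
    "classes": ["jogging", "walking", "ascent", "descent", "sitting", "standing"],
    "initial": [
      [100, 2, 0, 3, 0, 1],
      [0, 106, 0, 2, 0, 0],
      [3, 4, 85, 12, 0, 3],
      [3, 4, 8, 79, 5, 5],
      [0, 0, 0, 1, 60, 32],
      [0, 1, 0, 0, 10, 71]
    ],
    "enhanced": [
      [488, 3, 3, 1, 0, 0],
      [0, 546, 0, 5, 0, 0],
      [5, 6, 453, 8, 2, 4],
      [0, 6, 20, 457, 4, 8],
      [0, 0, 3, 1, 468, 19],
      [0, 0, 4, 2, 21, 463]
    ]
  },
  "local_hs_resnet50": {
    "classes": ["ascent", "descent", "walking", "standing"],
    "initial": [
      [9, 2, 1, 0],
      [2, 5, 0, 0],
      [0, 2, 11, 0],
      [0, 0, 0, 8]
    ],
    "enhanced": [
      [86, 0, 0, 0],
      [0, 95, 0, 0],
      [0, 0, 91, 0],
      [0, 0, 0, 87]
    ]
  },
  "local_pd_mobilenet_v2": {
    "classes": ["ascent", "descent", "walking", "standing"],
    "initial": [
      [15, 1, 0, 2],
      [1, 10, 0, 0],
      [0, 0, 13, 0],
      [0, 0, 0, 14]
    ],
    "enhanced": [
      [121, 1, 0, 2],
      [0, 99, 0, 0],
      [0, 0, 135, 0],
      [0, 0, 1, 145]
    ]
  },
  "local_ss_resnet50": {
    "classes": ["ascent", "descent", "walking", "standing"],
    "initial": [
      [1, 1, 1, 4],
      [0, 4, 0, 1],
      [0, 0, 12, 0],
      [1, 2, 0, 8]
    ],
    "enhanced": [
      [36, 0, 0, 3],
      [1, 51, 0, 1],
      [0, 0, 120, 0],
      [0, 1, 0, 99]
    ]
  }
}
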