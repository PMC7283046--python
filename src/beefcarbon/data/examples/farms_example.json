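{
  "farms": [
    {
      "cohorts": [
        {
          "avg_live_weight": 619.7839029899455,
          "category": "suckler_cow",
          "daily_gain": 0.0,
          "days_grazing": 251.3851296910221,
          "days_housed": 113.61487030897791,
          "gross_energy_intake": 174.09584487874935,
          "headcount": 40.0,
          "n_excretion": 84.06995778961303,
          "volatile_solids": 3.107233357797732
        },
        {
          "avg_live_weight": 216.12451945788519,
          "category": "weanling",
          "daily_gain": 0.8610365722028449,
          "days_grazing": 251.3851296910221,
          "days_housed": 113.61487030897791,
          "gross_energy_intake": 60.24626680883699,
          "headcount": 24.449334447656604,
          "n_excretion": 32.50364672630052,
          "volatile_solids": 1.1402043789930199
        },
        {
          "avg_live_weight": 419.1114584658981,
          "category": "store",
          "daily_gain": 0.8942211599403715,
          "days_grazing": 251.3851296910221,
          "days_housed": 113.61487030897791,
          "gross_energy_intake": 124.04142984159466,
          "headcount": 34.666966754139956,
          "n_excretion": 50.871849111603005,
          "volatile_solids": 2.1247361133284604
        },
        {
          "avg_live_weight": 542.1512963236297,
          "category": "finishing_steer",
          "daily_gain": 0.8642608035100507,
          "days_grazing": 120.0,
          "days_housed": 245.0,
          "gross_energy_intake": 149.24813533040333,
          "headcount": 9.122885987931568,
          "n_excretion": 52.741028783218184,
          "volatile_solids": 2.2695193674824625
        },
        {
          "avg_live_weight": 912.34897555375,
          "category": "breeding_bull",
          "daily_gain": 0.07766831143422981,
          "days_grazing": 251.3851296910221,
          "days_housed": 113.61487030897791,
          "gross_energy_intake": 203.3900990315912,
          "headcount": 1.2,
          "n_excretion": 103.34595409581806,
          "volatile_solids": 3.5277150136649422
        }
      ],
      "concentrate_fed": {
        "compound_ration": 25405.564355911225
      },
      "cropland_area": 0.0,
      "diesel_used": 6375.621396688569,
      "electricity_used": 2111.8314520104855,
      "farm_id": "EX1",
      "fert_n_applied": 6283.844732686677,
      "grassland_area": 72.28371899280616,
      "hedgerow_length": 1495.6385318275743,
      "lime_applied": 4767.201081597541,
      "lw_closing": 50645.58301031339,
      "lw_opening": 50645.58301031339,
      "lw_purchased": 0.0,
      "lw_sold": 20495.605088497516,
      "manure_system_shares": {
        "slurry_tank": 0.726053932602442,
        "solid_storage": 0.273946067397558
      },
      "system": "suckler_to_beef"
    },
    {
      "cohorts": [
        {
          "avg_live_weight": 583.0742962742723,
          "category": "finishing_bull",
          "daily_gain": 1.121277931716658,
          "days_grazing": 0.0,
          "days_housed": 365.0,
          "gross_energy_intake": 141.33744723701628,
          "headcount": 310.96000000000004,
          "n_excretion": 47.01062545870747,
          "volatile_solids": 2.4418677918682774
        }
      ],
      "concentrate_fed": {
        "cereal_mix": 247847.89345961166,
        "compound_ration": 454387.80467595474,
        "protein_mix": 123923.94672980583
      },
      "cropland_area": 58.008892364885426,
      "diesel_used": 3823.6039798168754,
      "electricity_used": 13001.686795054611,
      "farm_id": "EX2",
      "fert_n_applied": 11102.039388486139,
      "grassland_area": 0.0,
      "hedgerow_length": 274.7968438365298,
      "lime_applied": 191.84083605466097,
      "lw_closing": 181312.78316944774,
      "lw_opening": 181312.78316944774,
      "lw_purchased": 154769.6540948666,
      "lw_sold": 314626.39447806217,
      "manure_system_shares": {
        "slurry_tank": 0.6989195149497276,
        "solid_storage": 0.3010804850502724
      },
      "system": "beef_fattening"
    }
  ]
}
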