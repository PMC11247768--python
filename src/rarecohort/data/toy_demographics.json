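{
  "reference_year": 2020,
  "states": [
    {
      "state_code": "AA",
      "zip_codes": [
        "00000",
        "00001",
        "00002",
        "00003",
        "00004"
      ],
      "pop_by_age": {
        "0": 3163,
        "1": 3132,
        "2": 3007,
        "3": 3055,
        "4": 3135,
        "5": 3279,
        "6": 3351,
        "7": 3317,
        "8": 3316,
        "9": 3355,
        "10": 3252,
        "11": 3243,
        "12": 3303,
        "13": 3188,
        "14": 3157,
        "15": 3523,
        "16": 3416,
        "17": 3454,
        "18": 3565,
        "19": 3618,
        "20": 3493,
        "21": 3432,
        "22": 3440,
        "23": 3354,
        "24": 3427,
        "25": 3597,
        "26": 3650,
        "27": 3548,
        "28": 3547,
        "29": 3592,
        "30": 3621,
        "31": 3621,
        "32": 3565,
        "33": 3524,
        "34": 3620,
        "35": 3559,
        "36": 3546,
        "37": 3525,
        "38": 3602,
        "39": 3570,
        "40": 3216,
        "41": 3202,
        "42": 3165,
        "43": 3264,
        "44": 3206,
        "45": 3188,
        "46": 3131,
        "47": 3133,
        "48": 3217,
        "49": 3132,
        "50": 3212,
        "51": 3164,
        "52": 3136,
        "53": 3232,
        "54": 3198,
        "55": 3157,
        "56": 3190,
        "57": 3230,
        "58": 3302,
        "59": 3163,
        "60": 3156,
        "61": 2311,
        "62": 2285,
        "63": 2349,
        "64": 2381,
        "65": 2362,
        "66": 2340,
        "67": 2353,
        "68": 2331,
        "69": 2347,
        "70": 2399,
        "71": 2235,
        "72": 2316,
        "73": 2321,
        "74": 2341,
        "75": 2281,
        "76": 2302,
        "77": 2384,
        "78": 2396,
        "79": 2456,
        "80": 2383,
        "81": 2319,
        "82": 2404,
        "83": 2350,
        "84": 2263,
        "85+": 2399
      },
      "sex_percent": {
        "male": 49.92317960554304,
        "female": 50.07682039445696
      },
      "race_percent": {
        "African-American": 16.087771517911353,
        "European-American": 59.767905295707294,
        "Others": 24.144323186381357
      }
    },
    {
      "state_code": "AB",
      "zip_codes": [
        "00100",
        "00101",
        "00102",
        "00103",
        "00104",
        "00105",
        "00106",
        "00107"
      ],
      "pop_by_age": {
        "0": 6623,
        "1": 6531,
        "2": 6383,
        "3": 6583,
        "4": 6698,
        "5": 7053,
        "6": 7036,
        "7": 6985,
        "8": 6976,
        "9": 7013,
        "10": 7114,
        "11": 6954,
        "12": 7089,
        "13": 7056,
        "14": 7003,
        "15": 7478,
        "16": 7329,
        "17": 7400,
        "18": 7389,
        "19": 7440,
        "20": 7446,
        "21": 7363,
        "22": 7320,
        "23": 7441,
        "24": 7441,
        "25": 7753,
        "26": 7596,
        "27": 7698,
        "28": 7638,
        "29": 7761,
        "30": 7705,
        "31": 7498,
        "32": 7614,
        "33": 7756,
        "34": 7689,
        "35": 7674,
        "36": 7615,
        "37": 7771,
        "38": 7607,
        "39": 7616,
        "40": 6769,
        "41": 6812,
        "42": 6663,
        "43": 6863,
        "44": 6866,
        "45": 6742,
        "46": 6898,
        "47": 6784,
        "48": 6889,
        "49": 6897,
        "50": 6825,
        "51": 6816,
        "52": 6933,
        "53": 6844,
        "54": 6959,
        "55": 6830,
        "56": 6882,
        "57": 6877,
        "58": 6761,
        "59": 6797,
        "60": 6854,
        "61": 5149,
        "62": 4980,
        "63": 4975,
        "64": 4944,
        "65": 4901,
        "66": 5077,
        "67": 5015,
        "68": 5036,
        "69": 5016,
        "70": 4967,
        "71": 5113,
        "72": 5000,
        "73": 5062,
        "74": 5046,
        "75": 4968,
        "76": 4934,
        "77": 4865,
        "78": 5065,
        "79": 4927,
        "80": 5141,
        "81": 5098,
        "82": 4970,
        "83": 5006,
        "84": 4977,
        "85+": 4935
      },
      "sex_percent": {
        "male": 50.927559128551536,
        "female": 49.072440871448464
      },
      "race_percent": {
        "African-American": 15.30343736881864,
        "European-American": 62.91813599144952,
        "Others": 21.77842663973184
      }
    },
    {
      "state_code": "AC",
      "zip_codes": [
        "00200",
        "00201",
        "00202",
        "00203",
        "00204",
        "00205",
        "00206"
      ],
      "pop_by_age": {
        "0": 4482,
        "1": 4528,
        "2": 4427,
        "3": 4372,
        "4": 4306,
        "5": 4697,
        "6": 4676,
        "7": 4557,
        "8": 4731,
        "9": 4868,
        "10": 4758,
        "11": 4603,
        "12": 4749,
        "13": 4797,
        "14": 4810,
        "15": 4966,
        "16": 4949,
        "17": 5012,
        "18": 4957,
        "19": 5050,
        "20": 4894,
        "21": 4911,
        "22": 5058,
        "23": 5005,
        "24": 4991,
        "25": 5080,
        "26": 5126,
        "27": 5120,
        "28": 5198,
        "29": 5115,
        "30": 5239,
        "31": 5090,
        "32": 5119,
        "33": 5099,
        "34": 5236,
        "35": 5122,
        "36": 5324,
        "37": 5149,
        "38": 5131,
        "39": 5162,
        "40": 4499,
        "41": 4598,
        "42": 4592,
        "43": 4693,
        "44": 4564,
        "45": 4561,
        "46": 4602,
        "47": 4667,
        "48": 4565,
        "49": 4554,
        "50": 4597,
        "51": 4600,
        "52": 4646,
        "53": 4590,
        "54": 4448,
        "55": 4546,
        "56": 4614,
        "57": 4591,
        "58": 4641,
        "59": 4630,
        "60": 4374,
        "61": 3316,
        "62": 3320,
        "63": 3446,
        "64": 3350,
        "65": 3354,
        "66": 3377,
        "67": 3446,
        "68": 3294,
        "69": 3345,
        "70": 3417,
        "71": 3243,
        "72": 3432,
        "73": 3503,
        "74": 3388,
        "75": 3360,
        "76": 3449,
        "77": 3353,
        "78": 3385,
        "79": 3442,
        "80": 3308,
        "81": 3304,
        "82": 3455,
        "83": 3223,
        "84": 3344,
        "85+": 3383
      },
      "sex_percent": {
        "male": 50.637263819002385,
        "female": 49.362736180997615
      },
      "race_percent": {
        "African-American": 7.1346402180976165,
        "European-American": 61.93439085914265,
        "Others": 30.930968922759728
      }
    }
  ]
}
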