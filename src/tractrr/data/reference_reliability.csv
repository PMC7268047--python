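approach,metric,hemisphere,mean_day1,sd_day1,mean_day4,sd_day4,icc,ci_low,ci_high,rating,mdc95
peduncle,FA,ipsilesional,0.569,0.052,0.566,0.062,0.844,0.630,0.939,good,0.057
peduncle,FA,contralesional,0.624,0.044,0.628,0.046,0.786,0.513,0.914,good,0.056
peduncle,FA_ratio,derived,0.912,0.074,0.903,0.076,0.828,0.604,0.932,good,0.085
peduncle,FA_asymmetry,derived,0.048,0.041,0.053,0.042,0.833,0.614,0.934,good,0.046
peduncle,MD,ipsilesional,1.048,0.092,1.041,0.077,0.493,0.035,0.776,poor,0.182
peduncle,MD,contralesional,0.942,0.074,0.941,0.077,0.650,0.267,0.854,moderate,0.121
peduncle,AD,ipsilesional,1.760,0.152,1.749,0.125,0.764,0.472,0.905,good,0.205
peduncle,AD,contralesional,1.674,0.088,1.676,0.075,0.740,0.423,0.895,moderate,0.125
peduncle,RD,ipsilesional,0.693,0.085,0.688,0.089,0.526,0.079,0.794,moderate,0.162
peduncle,RD,contralesional,0.576,0.084,0.574,0.092,0.707,0.363,0.880,moderate,0.126
probabilistic,FA,ipsilesional,0.461,0.033,0.459,0.032,0.973,0.930,0.990,excellent,0.015
probabilistic,FA,contralesional,0.490,0.021,0.489,0.019,0.970,0.922,0.988,excellent,0.010
probabilistic,FA_ratio,derived,0.939,0.043,0.938,0.040,0.936,0.837,0.975,excellent,0.030
probabilistic,FA_asymmetry,derived,0.032,0.023,0.032,0.021,0.932,0.828,0.974,excellent,0.017
probabilistic,MD,ipsilesional,0.842,0.072,0.844,0.071,0.986,0.965,0.995,excellent,0.023
probabilistic,MD,contralesional,0.767,0.022,0.767,0.023,0.951,0.873,0.981,excellent,0.014
probabilistic,AD,ipsilesional,1.297,0.098,1.299,0.097,0.993,0.982,0.997,excellent,0.023
probabilistic,AD,contralesional,1.222,0.036,1.221,0.031,0.944,0.856,0.979,excellent,0.024
probabilistic,RD,ipsilesional,0.614,0.066,0.617,0.066,0.980,0.948,0.992,excellent,0.026
probabilistic,RD,contralesional,0.539,0.024,0.540,0.025,0.965,0.910,0.987,excellent,0.013
template,FA,ipsilesional,0.422,0.025,0.422,0.025,0.984,0.958,0.994,excellent,0.009
template,FA,contralesional,0.455,0.020,0.453,0.020,0.976,0.930,0.992,excellent,0.009
template,FA_ratio,derived,0.928,0.040,0.932,0.038,0.977,0.927,0.992,excellent,0.017
template,FA_asymmetry,derived,0.038,0.022,0.036,0.020,0.975,0.923,0.991,excellent,0.009
template,MD,ipsilesional,0.837,0.071,0.839,0.068,0.987,0.966,0.995,excellent,0.022
template,MD,contralesional,0.765,0.020,0.770,0.019,0.877,0.667,0.954,good,0.020
template,AD,ipsilesional,1.243,0.087,1.246,0.086,0.989,0.971,0.996,excellent,0.025
template,AD,contralesional,1.177,0.023,1.182,0.027,0.882,0.694,0.956,good,0.022
template,RD,ipsilesional,0.634,0.065,0.635,0.063,0.986,0.963,0.995,excellent,0.021
template,RD,contralesional,0.559,0.025,0.564,0.024,0.926,0.778,0.974,excellent,0.019
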