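name,chi0,chi1,chi2,chi3c,chi4pc,chi0v,chi1v,chi2v,chi3cv,chi4pcv,logcmc
bis(EA-11-3)C5,40.342595,25.83567,21.71634,3.77304,4.01125,37.06539,22.87411,17.76306,2.693502,2.6531996,-4.31158
bis(EA-11-3)C6,41.049702,26.33567,22.069896,3.77304,4.01125,37.772499,23.37411,18.11661,2.693502,2.6531996,-4.34969
bis(EA-11-3)C8,42.46392,27.33567,22.77,3.77304,4.01125,39.18671,24.37411,18.82372,2.693502,2.6531996,-4.39041
bis(EA-9-3iso)C6,38.54755,24.17711,20.76965,3.86803,6.47149,35.270345,21.22925,16.85702,2.77846,4.74458,-4.07469
bis(EA-9-3iso)C8,39.96176,25.17711,21.47676,3.86803,6.47149,36.68456,22.22925,17.56413,2.77846,4.74458,-4.10568
bis(EA-11-3iso)C5,40.66887,25.67711,21.83031,3.86803,6.47149,37.39167,22.72925,17.91768,2.77846,4.74458,-4.20204
bis(EA-11-3iso)C6,41.37598,26.17711,22.18386,3.86803,6.47149,38.09877,23.22925,18.27124,2.77846,4.74458,-4.22841
bis(EA-11-3iso)C8,42.79019,27.17711,22.89097,3.86803,6.47149,39.51299,24.22925,18.97834,2.77846,4.74458,-4.266803
C12AC2AC12,28.53948,18.16987,14.92768,2.509202,4.85064,26.68149,16.39809,12.64503,1.80341,2.18671,-3.02687
C12AC6AC12,31.367904,20.16987,16.34189,2.509202,4.85064,29.50991,18.39809,14.05924,1.80341,2.18671,-3.07058
C12AC12AC12,35.61054,23.16987,18.46321,2.509202,4.85064,33.75255,21.39809,16.18056,1.80341,2.18671,-3.65758
C12C6C12,26.79899,17.32843,14.1066,2.41421,2.41421,26.69342,16.96798,13.544065,2.15934,2.15934,-2.88606
C12EC6EC12,31.367904,20.16987,16.34189,2.509202,4.85064,29.32641,18.17658,13.82412,1.78666,2.03045,-3.11351
AC12C6C12A,32.78212,21.11612,17.50965,2.99156,2.88963,30.92413,19.29044,15.11298,2.30368,2.00972,-3.46852
AC12C12C12A,37.02476,24.11612,19.63097,2.99156,2.88963,35.16677,22.29044,17.23431,2.30368,2.00972,-3.79588
EC12C6C12E,32.78212,21.11612,17.50965,2.99156,2.88963,30.74062,19.06893,14.85402,2.27719,1.97915,-3.49485
AC12AC6AC12A,37.35103,23.95756,19.74494,3.08655,5.34987,33.74062,20.72055,15.62816,1.94775,2.09135,-3.60206
2a,30.82393,19.54797,16.55666,3.19569,3.25454,29.48265,18.27316,14.70763,2.57565,2.53284,-3.12843
2b,31.53104,20.04797,16.93708,3.19569,3.19475,30.18976,18.77316,15.11501,2.57565,2.48653,-3.204815
2c,32.23815,20.54797,17.29064,3.19569,3.19475,30.896865,19.27316,15.46856,2.57565,2.48653,-3.25104
2d,32.94525,21.04797,17.64419,3.19569,3.19475,31.60397,19.77316,15.82212,2.57565,2.48653,-3.40561
2e,33.65236,21.54797,17.997745,3.19569,3.19475,32.31108,20.27316,16.17567,2.57565,2.48653,-3.50169
2f,35.06657,22.54797,18.70485,3.19569,3.19475,33.72529,21.27316,16.882775,2.57565,2.48653,-3.598599
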