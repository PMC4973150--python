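site,strategy,year,row,count,printed_pct
colorectal,non_restrictive,2008,missing,6996,22.1
colorectal,non_restrictive,2009,missing,6408,19.8
colorectal,non_restrictive,2010,missing,5114,15.7
colorectal,non_restrictive,2011,missing,4777,14.3
colorectal,non_restrictive,2012,missing,3191,9.4
colorectal,non_restrictive,total,missing,26486,16.2
colorectal,non_restrictive,2008,observed,24630,77.9
colorectal,non_restrictive,2009,observed,25939,80.2
colorectal,non_restrictive,2010,observed,27518,84.3
colorectal,non_restrictive,2011,observed,28708,85.7
colorectal,non_restrictive,2012,observed,30634,90.6
colorectal,non_restrictive,total,observed,137429,83.8
colorectal,non_restrictive,2008,I,3774,15.3
colorectal,non_restrictive,2009,I,4159,16.0
colorectal,non_restrictive,2010,I,4602,16.7
colorectal,non_restrictive,2011,I,5043,17.6
colorectal,non_restrictive,2012,I,5803,18.9
colorectal,non_restrictive,total,I,23381,17.0
colorectal,non_restrictive,2008,II,7631,31.0
colorectal,non_restrictive,2009,II,7612,29.3
colorectal,non_restrictive,2010,II,7764,28.2
colorectal,non_restrictive,2011,II,7944,27.7
colorectal,non_restrictive,2012,II,8195,26.8
colorectal,non_restrictive,total,II,39146,28.5
colorectal,non_restrictive,2008,III,7890,32.0
colorectal,non_restrictive,2009,III,8212,31.7
colorectal,non_restrictive,2010,III,8495,30.9
colorectal,non_restrictive,2011,III,8508,29.6
colorectal,non_restrictive,2012,III,8432,27.5
colorectal,non_restrictive,total,III,41537,30.2
colorectal,non_restrictive,2008,IV,5335,21.7
colorectal,non_restrictive,2009,IV,5956,23.0
colorectal,non_restrictive,2010,IV,6657,24.2
colorectal,non_restrictive,2011,IV,7213,25.1
colorectal,non_restrictive,2012,IV,8204,26.8
colorectal,non_restrictive,total,IV,33365,24.3
colorectal,restrictive,2008,missing,20948,66.2
colorectal,restrictive,2009,missing,19360,59.9
colorectal,restrictive,2010,missing,15071,46.2
colorectal,restrictive,2011,missing,10749,32.1
colorectal,restrictive,2012,missing,5009,14.8
colorectal,restrictive,total,missing,71137,43.4
colorectal,restrictive,2008,observed,10678,33.8
colorectal,restrictive,2009,observed,12987,40.1
colorectal,restrictive,2010,observed,17561,53.8
colorectal,restrictive,2011,observed,22736,67.9
colorectal,restrictive,2012,observed,28816,85.2
colorectal,restrictive,total,observed,92778,56.6
colorectal,restrictive,2008,I,1046,9.8
colorectal,restrictive,2009,I,1434,11.0
colorectal,restrictive,2010,I,2333,13.3
colorectal,restrictive,2011,I,3637,16.0
colorectal,restrictive,2012,I,5117,17.8
colorectal,restrictive,total,I,13567,14.6
colorectal,restrictive,2008,II,2175,20.4
colorectal,restrictive,2009,II,2684,20.7
colorectal,restrictive,2010,II,4169,23.7
colorectal,restrictive,2011,II,5883,25.9
colorectal,restrictive,2012,II,7645,26.5
colorectal,restrictive,total,II,22556,24.3
colorectal,restrictive,2008,III,2759,25.8
colorectal,restrictive,2009,III,3455,26.6
colorectal,restrictive,2010,III,4839,27.6
colorectal,restrictive,2011,III,6408,28.2
colorectal,restrictive,2012,III,7970,27.7
colorectal,restrictive,total,III,25431,27.4
colorectal,restrictive,2008,IV,4698,44.0
colorectal,restrictive,2009,IV,5414,41.7
colorectal,restrictive,2010,IV,6220,35.4
colorectal,restrictive,2011,IV,6808,29.9
colorectal,restrictive,2012,IV,8084,28.1
colorectal,restrictive,total,IV,31224,33.7
colorectal,all,2008,total,31626,
colorectal,all,2009,total,32347,
colorectal,all,2010,total,32632,
colorectal,all,2011,total,33485,
colorectal,all,2012,total,33825,
colorectal,all,total,total,163915,
lung,non_restrictive,2008,missing,11498,35.9
lung,non_restrictive,2009,missing,8242,25.0
lung,non_restrictive,2010,missing,5622,16.8
lung,non_restrictive,2011,missing,3938,11.4
lung,non_restrictive,2012,missing,2441,6.9
lung,non_restrictive,total,missing,31741,18.9
lung,non_restrictive,2008,observed,20509,64.1
lung,non_restrictive,2009,observed,24765,75.0
lung,non_restrictive,2010,observed,27846,83.2
lung,non_restrictive,2011,observed,30463,88.6
lung,non_restrictive,2012,observed,32834,93.1
lung,non_restrictive,total,observed,136417,81.1
lung,non_restrictive,2008,I,2888,14.1
lung,non_restrictive,2009,I,3560,14.4
lung,non_restrictive,2010,I,3713,13.3
lung,non_restrictive,2011,I,4092,13.4
lung,non_restrictive,2012,I,4871,14.8
lung,non_restrictive,total,I,19124,14.0
lung,non_restrictive,2008,II,1303,6.4
lung,non_restrictive,2009,II,1661,6.7
lung,non_restrictive,2010,II,2221,8.0
lung,non_restrictive,2011,II,2509,8.2
lung,non_restrictive,2012,II,2764,8.4
lung,non_restrictive,total,II,10458,7.7
lung,non_restrictive,2008,III,6338,30.9
lung,non_restrictive,2009,III,7204,29.1
lung,non_restrictive,2010,III,7030,25.2
lung,non_restrictive,2011,III,7211,23.7
lung,non_restrictive,2012,III,7623,23.2
lung,non_restrictive,total,III,35406,26.0
lung,non_restrictive,2008,IV,9980,48.7
lung,non_restrictive,2009,IV,12340,49.8
lung,non_restrictive,2010,IV,14882,53.4
lung,non_restrictive,2011,IV,16651,54.7
lung,non_restrictive,2012,IV,17576,53.5
lung,non_restrictive,total,IV,71429,52.4
lung,restrictive,2008,missing,13661,42.7
lung,restrictive,2009,missing,10143,30.7
lung,restrictive,2010,missing,7321,21.9
lung,restrictive,2011,missing,5121,14.9
lung,restrictive,2012,missing,3046,8.6
lung,restrictive,total,missing,39292,23.4
lung,restrictive,2008,observed,18346,57.3
lung,restrictive,2009,observed,22864,69.3
lung,restrictive,2010,observed,26147,78.1
lung,restrictive,2011,observed,29280,85.1
lung,restrictive,2012,observed,32229,91.4
lung,restrictive,total,observed,128866,76.6
lung,restrictive,2008,I,2223,12.1
lung,restrictive,2009,I,2952,12.9
lung,restrictive,2010,I,3237,12.4
lung,restrictive,2011,I,3781,12.9
lung,restrictive,2012,I,4703,14.6
lung,restrictive,total,I,16896,13.1
lung,restrictive,2008,II,1060,5.8
lung,restrictive,2009,II,1455,6.4
lung,restrictive,2010,II,2030,7.8
lung,restrictive,2011,II,2383,8.1
lung,restrictive,2012,II,2696,8.4
lung,restrictive,total,II,9624,7.5
lung,restrictive,2008,III,5357,29.2
lung,restrictive,2009,III,6434,28.1
lung,restrictive,2010,III,6531,25.0
lung,restrictive,2011,III,6894,23.5
lung,restrictive,2012,III,7437,23.1
lung,restrictive,total,III,32653,25.3
lung,restrictive,2008,IV,9706,52.9
lung,restrictive,2009,IV,12023,52.6
lung,restrictive,2010,IV,14349,54.9
lung,restrictive,2011,IV,16222,55.4
lung,restrictive,2012,IV,17393,54.0
lung,restrictive,total,IV,69693,54.1
lung,all,2008,total,32007,
lung,all,2009,total,33007,
lung,all,2010,total,33468,
lung,all,2011,total,34401,
lung,all,2012,total,35275,
lung,all,total,total,168158,
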