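scenario,day,quantity,printed
2018,50,n_feed_t,0.006
2018,80,n_feed_t,0.148
2018,110,n_feed_t,0.271
2018,50,p_feed_t,0.0013
2018,80,p_feed_t,0.032
2018,110,p_feed_t,0.058
2018,50,unconsumed_n_t,0.0024
2018,80,unconsumed_n_t,0.045
2018,110,unconsumed_n_t,0.081
2018,50,unconsumed_p_t,0.0005
2018,80,unconsumed_p_t,0.0096
2018,110,unconsumed_p_t,0.0175
2018,50,meat_n_t,0.0035
2018,80,meat_n_t,0.0472
2018,110,meat_n_t,0.0861
2018,50,meat_p_t,0.0012
2018,80,meat_p_t,0.0157
2018,110,meat_p_t,0.0287
2018,50,excreted_n_t,0.0026
2018,80,excreted_n_t,0.101
2018,110,excreted_n_t,0.184
2018,50,excreted_p_t,0.00014
2018,80,excreted_p_t,0.0162
2018,110,excreted_p_t,0.03
2018,50,inorganic_n_load_t,0.005
2018,80,inorganic_n_load_t,0.146
2018,110,inorganic_n_load_t,0.266
2018,50,inorganic_p_load_t,0.00066
2018,80,inorganic_p_load_t,0.0258
2018,110,inorganic_p_load_t,0.047
2021,50,n_feed_t,0.0025
2021,80,n_feed_t,0.06
2021,110,n_feed_t,0.105
2021,50,p_feed_t,0.00054
2021,80,p_feed_t,0.0129
2021,110,p_feed_t,0.0226
2021,50,unconsumed_n_t,0.00025
2021,80,unconsumed_n_t,0.006
2021,110,unconsumed_n_t,0.0105
2021,50,unconsumed_p_t,0.000055
2021,80,unconsumed_p_t,0.0013
2021,110,unconsumed_p_t,0.0023
2021,50,meat_n_t,0.0015
2021,80,meat_n_t,0.0197
2021,110,meat_n_t,0.036
2021,50,meat_p_t,0.00049
2021,80,meat_p_t,0.0066
2021,110,meat_p_t,0.012
2021,50,excreted_n_t,0.0011
2021,80,excreted_n_t,0.04
2021,110,excreted_n_t,0.069
2021,50,excreted_p_t,0.00006
2021,80,excreted_p_t,0.0063
2021,110,excreted_p_t,0.011
2021,50,inorganic_n_load_t,0.0013
2021,80,inorganic_n_load_t,0.046
2021,110,inorganic_n_load_t,0.08
2021,50,inorganic_p_load_t,0.0001
2021,80,inorganic_p_load_t,0.0076
2021,110,inorganic_p_load_t,0.013
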